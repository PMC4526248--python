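"""End-to-end orchestration: simulate -> detect -> score -> analyze.

A run is fully determined by a :class:`RunConfig`; one master seed derives
every stage seed (hash of seed, stage name and participant id), so reruns
with the same config reproduce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DegenerateDataError, GaitsyncError, ValidationError
from .metrics import HEAD_TRIM_S, compute_metrics
from .protocol import LAP_DISTANCE_M, RAMP_S, REFERENCE_WINDOW_S, SHIFTS
from .simulate import CohortConfig, SimulatedDataset, simulate_cohort
from .stats import (
    basin_analysis,
    friedman,
    ks_normality,
    mann_whitney,
    rm_anova_linear,
    spearman,
)

log = logging.getLogger("gaitsync")

#: RunConfig defaults, also the reference for validate_config
DEFAULTS = {
    "seed": 0,
    "shifts": list(SHIFTS),
    "laps_per_sequence": 4,
    "lap_distance_m": LAP_DISTANCE_M,
    "n_sequences": 12,
    "ramp_s": RAMP_S,
    "reference_window_s": REFERENCE_WINDOW_S,
    "sample_rate": 100.0,
    "accel_noise_sd": 0.5,
    "use_detected": True,
    "write_accel": False,
    "verbosity": "info",
    "cohort": {},
}


@dataclass
class RunConfig:
    """Normalized configuration of one pipeline run."""

    cohort: CohortConfig
    seed: int = 0
    shifts: tuple[float, ...] = SHIFTS
    laps_per_sequence: int = 4
    lap_distance_m: float = LAP_DISTANCE_M
    n_sequences: int = 12
    ramp_s: float = RAMP_S
    reference_window_s: float = REFERENCE_WINDOW_S
    sample_rate: float = 100.0
    accel_noise_sd: float = 0.5
    use_detected: bool = True
    write_accel: bool = False
    verbosity: str = "info"
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("warnings")
        d["shifts"] = list(self.shifts)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(config: dict | None) -> RunConfig:
    """Fill defaults, check consistency, and normalize a config mapping.

    Raises ValidationError with all problems aggregated into one message;
    non-fatal inconsistencies (e.g. a tempo ramp longer than the 5 s head
    trim, which would leak ramp tempos into the analysis window) are
    collected as warnings on the returned config.
    """
    cfg = dict(config or {})
    errors: list[str] = []
    warnings: list[str] = []

    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        errors.append(f"unknown config key(s): {sorted(unknown)}")
    merged = {**DEFAULTS, **{k: v for k, v in cfg.items() if k in DEFAULTS}}

    seed = merged["seed"]
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        errors.append(f"seed must be a non-negative integer, got {seed!r}")
    shifts = tuple(float(s) for s in merged["shifts"])
    if len(shifts) != len(set(shifts)):
        errors.append("shifts must be distinct")
    if merged["ramp_s"] < 0:
        errors.append("ramp_s must be >= 0")
    elif merged["ramp_s"] > HEAD_TRIM_S:
        warnings.append(
            f"ramp_s {merged['ramp_s']} exceeds the {HEAD_TRIM_S:.0f} s head trim: "
            "ramp tempos leak into the analyzed window"
        )
    if merged["lap_distance_m"] <= 0:
        errors.append("lap_distance_m must be positive")
    if merged["sample_rate"] < 20:
        errors.append("sample_rate must be >= 20 Hz")
    if merged["laps_per_sequence"] != 4:
        errors.append("protocol requires 4 laps per sequence")

    cohort_cfg = dict(merged["cohort"] or {})
    try:
        if isinstance(seed, (int, np.integer)) and "seed" not in cohort_cfg:
            cohort_cfg["seed"] = int(seed)
        cohort = CohortConfig(**cohort_cfg)
    except (TypeError, ValidationError) as err:
        errors.append(f"cohort: {err}")
        cohort = CohortConfig()

    if errors:
        raise ValidationError("invalid config:\n  - " + "\n  - ".join(errors))
    return RunConfig(
        cohort=cohort,
        seed=int(seed),
        shifts=shifts,
        laps_per_sequence=int(merged["laps_per_sequence"]),
        lap_distance_m=float(merged["lap_distance_m"]),
        n_sequences=int(merged["n_sequences"]),
        ramp_s=float(merged["ramp_s"]),
        reference_window_s=float(merged["reference_window_s"]),
        sample_rate=float(merged["sample_rate"]),
        accel_noise_sd=float(merged["accel_noise_sd"]),
        use_detected=bool(merged["use_detected"]),
        write_accel=bool(merged["write_accel"]),
        verbosity=str(merged["verbosity"]),
        warnings=warnings,
    )


def analyze_metrics(metrics: pd.DataFrame, profiles: pd.DataFrame | None = None) -> dict:
    """Run the statistical battery on a tidy metric table.

    Tests whose preconditions the data cannot meet (e.g. a single
    condition) are reported as skipped rather than aborting the run.
    """
    report: dict = {}

    def guarded(name, fn):
        t0 = time.perf_counter()
        try:
            report[name] = fn()
            log.info("analyze: %s done in %.2f s", name, time.perf_counter() - t0)
        except (GaitsyncError, ValueError) as err:
            report[name] = {"skipped": str(err)}
            log.info("analyze: %s skipped (%s)", name, err)

    shifts = sorted(metrics["shift_pct"].unique())
    adapt = metrics.pivot(index="participant_id", columns="shift_pct", values="adaptation_pct")
    entr = metrics.pivot(index="participant_id", columns="shift_pct", values="entrainment_pct")

    guarded("normality_adaptation", lambda: ks_normality(metrics["adaptation_pct"].to_numpy()).to_dict())
    guarded("normality_entrainment", lambda: ks_normality(metrics["entrainment_pct"].to_numpy()).to_dict())

    def _anova():
        omni, contrast = rm_anova_linear(adapt[shifts].to_numpy(), shifts)
        return {"omnibus": omni.to_dict(), "linear_contrast": contrast.to_dict()}

    guarded("rm_anova_adaptation", _anova)
    guarded("friedman_entrainment", lambda: friedman(entr[shifts].to_numpy()).to_dict())
    guarded("basin", lambda: basin_analysis(metrics).to_dict())
    guarded(
        "spearman_entrainment_rpe",
        lambda: spearman(metrics["entrainment_pct"].to_numpy(), metrics["rpe"].to_numpy()).to_dict(),
    )

    if profiles is not None:
        merged = metrics.merge(
            profiles[["id", "gender", "musical_training"]],
            left_on="participant_id",
            right_on="id",
        )
        per_part = merged.groupby(["participant_id", "gender", "musical_training"], as_index=False)[
            ["entrainment_pct", "adaptation_pct"]
        ].mean()

        def _gender():
            f = per_part.loc[per_part.gender == "female", "entrainment_pct"].to_numpy()
            m = per_part.loc[per_part.gender == "male", "entrainment_pct"].to_numpy()
            res = mann_whitney(f, m).to_dict()
            res["median_female"] = float(np.median(f))
            res["median_male"] = float(np.median(m))
            return res

        def _training():
            a = per_part.loc[per_part.musical_training, "entrainment_pct"].to_numpy()
            b = per_part.loc[~per_part.musical_training.astype(bool), "entrainment_pct"].to_numpy()
            res = mann_whitney(a, b).to_dict()
            res["median_trained"] = float(np.median(a)) if len(a) else None
            res["median_untrained"] = float(np.median(b)) if len(b) else None
            return res

        def _slopes():
            # descriptive: per-gender slope of mean adaptation vs shift
            out = {}
            for g, grp in merged.groupby("gender"):
                means = grp.groupby("shift_pct")["adaptation_pct"].mean()
                if len(means) >= 2:
                    out[g] = float(np.polyfit(means.index.to_numpy(), means.to_numpy(), 1)[0])
            return out

        guarded("mann_whitney_gender", _gender)
        guarded("mann_whitney_training", _training)
        guarded("adaptation_slope_by_gender", _slopes)

    return report


def condition_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean, SE and median of both outcome measures."""
    g = metrics.groupby("shift_pct")

    def se(x):
        return x.std(ddof=1) / np.sqrt(len(x))

    out = g.agg(
        adaptation_mean=("adaptation_pct", "mean"),
        adaptation_se=("adaptation_pct", se),
        adaptation_median=("adaptation_pct", "median"),
        entrainment_mean=("entrainment_pct", "mean"),
        entrainment_se=("entrainment_pct", se),
        entrainment_median=("entrainment_pct", "median"),
        n=("participant_id", "count"),
    ).reset_index()
    return out


def run_experiment(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline into ``outdir``; returns the manifest.

    Artifacts: ``dataset/`` (profiles, schedules, step series, sequence
    metadata), ``metrics.csv``, ``summary.csv``, ``stats_report.json``,
    ``run.log`` and ``manifest.json`` (config hash + version).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.DEBUG if config.verbosity == "debug" else logging.INFO)
    try:
        for w in config.warnings:
            log.warning("config: %s", w)

        t0 = time.perf_counter()
        dataset = simulate_cohort(
            config.cohort,
            synth_traces=config.use_detected,
            accel_noise_sd=config.accel_noise_sd,
            sample_rate=config.sample_rate,
            ramp_s=config.ramp_s,
            lap_distance_m=config.lap_distance_m,
            shifts=config.shifts,
        )
        log.info(
            "simulate: %d participants, %d sequences in %.2f s",
            config.cohort.n_participants,
            len(dataset.records),
            time.perf_counter() - t0,
        )
        dataset.export(outdir / "dataset", write_accel=config.write_accel)

        t0 = time.perf_counter()
        metrics = compute_metrics(dataset, use_detected=config.use_detected)
        log.info(
            "detect+score: %d metric rows (%s steps) in %.2f s",
            len(metrics),
            "detected" if config.use_detected else "true",
            time.perf_counter() - t0,
        )
        metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")
        condition_summary(metrics).to_csv(outdir / "summary.csv", index=False, float_format="%.6f")

        t0 = time.perf_counter()
        report = analyze_metrics(metrics, profiles=dataset.profile_frame())
        log.info("analyze: report with %d entries in %.2f s", len(report), time.perf_counter() - t0)
        (outdir / "stats_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_metric_rows": int(len(metrics)),
            "warnings": config.warnings,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
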