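"""Synthetic runners: phase-correction gait model, accelerometer synthesis, cohorts.

The gait model is a stochastic circle map.  A runner produces steps at a
preferred period T_s = 60/preferred_cadence.  While music plays, each step's
asynchrony to the nearest beat (relative phase phi, in cycles, wrapped to
(-0.5, 0.5]) feeds back on the next inter-step interval:

    interval = T_s - (K * T_b / 2pi) * sin(2pi * phi) + N(0, motor_noise_sd)

with T_b the local beat period.  This sinusoidal phase-error correction
yields a finite entrainment basin (an Arnold tongue): the noiseless map has
a stable fixed point — the runner phase-locks to the beat — exactly when
the relative detuning |T_s/T_b - 1| is below K/(2pi).  Outside that basin
the phase drifts and the cadence stays near the runner's own.

Accelerometer traces emulate an ankle-worn sensor streaming at 100 Hz:
each step stamps a biphasic Gaussian-windowed impulse on the vertical axis
over a gravity baseline, with white noise on all three axes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AliasingError, ValidationError
from .protocol import (
    LAP_DISTANCE_M,
    LAPS_PER_SEQUENCE,
    SessionSchedule,
    TempoTimeline,
    build_timeline,
    make_cohort_schedules,
    reference_cadence,
)
from .steps import StepSeries
from .stimuli import BmriRating, EligibilityError, StimulusLibrary, packaged_library, pick_song, select_playlist

TWO_PI = 2.0 * np.pi

#: hard floor on a simulated inter-step interval, seconds (300 SPM)
MIN_INTERVAL_S = 0.2

#: impulse width parameter (Gaussian sigma), seconds
IMPULSE_SIGMA_S = 0.02

#: default vertical impulse peak, m/s^2
IMPULSE_AMPLITUDE = 8.0

#: standard gravity baseline on the vertical axis, m/s^2
GRAVITY = 9.81


def derive_seed(master: int, *tokens) -> int:
    """Stable stage seed from a master seed and string tokens (< 2^31)."""
    h = hashlib.sha256(("/".join([str(int(master))] + [str(t) for t in tokens])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunnerProfile:
    """One synthetic runner.

    ``coupling`` is the circle-map gain K (dimensionless); the runner's
    entrainment-basin half-width in relative detuning is K/(2pi).
    """

    id: str
    preferred_cadence: float  # SPM
    coupling: float  # K >= 0
    motor_noise_sd: float = 0.010  # seconds
    gender: str = "female"
    musical_training: bool = False
    speed: float = 2.78  # m/s, sets self-paced lap duration

    def __post_init__(self):
        if not 130.0 <= self.preferred_cadence <= 200.0:
            raise ValidationError(
                f"preferred_cadence {self.preferred_cadence} outside 130-200 SPM"
            )
        if self.coupling < 0 or self.motor_noise_sd < 0:
            raise ValidationError("coupling and motor_noise_sd must be >= 0")
        if self.gender not in ("female", "male"):
            raise ValidationError("gender must be 'female' or 'male'")

    @property
    def basin_halfwidth_pct(self) -> float:
        """Predicted entrainment-basin half-width, percent detuning."""
        return 100.0 * self.coupling / TWO_PI


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study group: 16 recreational runners, 9 female and
    7 male.  Women are given a higher mean coupling than men (0.16 vs 0.09),
    reproducing the direction of the observed gender effect on entrainment;
    these are free simulator parameters, not estimates.  62.5 % of the
    cohort is flagged musically trained.
    """

    n_female: int = 9
    n_male: int = 7
    coupling_mean_female: float = 0.16
    coupling_mean_male: float = 0.09
    coupling_sd: float = 0.03
    cadence_mean: float = 160.0  # SPM
    cadence_sd: float = 10.0
    motor_noise_sd: float = 0.010  # seconds
    training_fraction: float = 0.625
    speed_mean: float = 2.78  # m/s
    speed_sd: float = 0.25
    rpe_mean: float = 13.0
    rpe_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if min(self.coupling_sd, self.cadence_sd, self.motor_noise_sd, self.speed_sd, self.rpe_sd) < 0:
            raise ValidationError("dispersions must be >= 0")
        if not 0.0 <= self.training_fraction <= 1.0:
            raise ValidationError("training_fraction must be in [0, 1]")
        if self.n_female < 0 or self.n_male < 0 or self.n_female + self.n_male == 0:
            raise ValidationError("cohort must contain at least one runner")

    @property
    def n_participants(self) -> int:
        return self.n_female + self.n_male


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration, m/s^2."""

    sample_rate: float
    t0: float
    samples: np.ndarray  # (n, 3): ax, ay, az

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError("samples must have shape (n, 3)")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[0]) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "ax": self.samples[:, 0], "ay": self.samples[:, 1], "az": self.samples[:, 2]}
        )


def simulate_steps(
    runner: RunnerProfile,
    timeline: TempoTimeline | None,
    seed: int,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> StepSeries:
    """Generate step times for one four-lap sequence.

    ``timeline=None`` (or laps with no music) runs the uncoupled gait:
    preferred period plus motor noise.  With music, the circle-map update
    in the module docstring applies at every step that falls inside the
    music interval.  K = 0 reduces exactly to the uncoupled gait.
    """
    if t_end is None:
        if timeline is None:
            raise ValidationError("t_end is required when no timeline is given")
        t_end = timeline.end
    rng = np.random.default_rng(seed)
    T_s = 60.0 / runner.preferred_cadence
    beats = timeline.beat_times() if timeline is not None else np.empty(0)

    times = []
    t = t_start + rng.uniform(0.0, T_s)  # random initial step phase
    while t < t_end:
        times.append(t)
        interval = T_s
        if timeline is not None and len(beats):
            bpm = timeline.bpm_at(t)
            if np.isfinite(bpm):
                T_b = 60.0 / bpm
                i = int(np.searchsorted(beats, t))
                cand = beats[max(i - 1, 0) : i + 1]
                nearest = cand[np.argmin(np.abs(cand - t))]
                phi = (t - nearest) / T_b
                phi -= np.round(phi)
                if phi <= -0.5:
                    phi += 1.0
                interval = T_s - (runner.coupling * T_b / TWO_PI) * np.sin(TWO_PI * phi)
        if runner.motor_noise_sd > 0:
            interval += rng.normal(0.0, runner.motor_noise_sd)
        t += max(interval, MIN_INTERVAL_S)
    return StepSeries(step_times=np.asarray(times))


def synth_accel(
    step_series: StepSeries,
    sample_rate: float = 100.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    t0: float = 0.0,
    duration: float | None = None,
    amplitude: float = IMPULSE_AMPLITUDE,
) -> AccelTrace:
    """Synthesize a tri-axial trace from a step train.

    Each step adds, on the vertical axis, a main Gaussian lobe peaked at
    the step time followed by a half-amplitude negative rebound (biphasic,
    ~80 ms overall width) over the gravity baseline.  The peak is kept at
    least 5x ``noise_sd``.  White Gaussian noise goes on all three axes.

    Raises
    ------
    AliasingError
        if ``sample_rate`` is at or below twice the mean step rate.
    """
    if len(step_series) == 0:
        raise ValidationError("step series is empty")
    st = step_series.step_times
    if len(st) >= 2:
        f_step = (len(st) - 1) / (st[-1] - st[0])
        if sample_rate <= 2.0 * f_step:
            raise AliasingError(
                f"sample rate {sample_rate} Hz <= 2x step rate {f_step:.2f} Hz"
            )
    if duration is None:
        duration = (st[-1] - t0) + 0.5
    n = int(round(duration * sample_rate))
    amp = max(amplitude, 5.0 * noise_sd)

    az = np.full(n, GRAVITY)
    sigma = IMPULSE_SIGMA_S
    half = int(np.ceil(6 * sigma * sample_rate))
    u_rel = np.arange(-half, half + 1)
    for t_k in st:
        center = (t_k - t0) * sample_rate
        c = int(round(center))
        u = (u_rel + c - center) / (sigma * sample_rate)
        pulse = amp * (np.exp(-0.5 * u**2) - 0.5 * np.exp(-0.5 * (u - 2.5) ** 2))
        lo, hi = c - half, c + half + 1
        plo, phi_ = max(0, -lo), len(pulse) - max(0, hi - n)
        if plo < phi_:
            az[max(lo, 0) : min(hi, n)] += pulse[plo:phi_]

    samples = np.zeros((n, 3))
    samples[:, 2] = az
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples += rng.normal(0.0, noise_sd, size=(n, 3))
    return AccelTrace(sample_rate=sample_rate, t0=t0, samples=samples)


@dataclass
class SequenceRecord:
    """Everything simulated for one participant x sequence."""

    participant_id: str
    sequence_index: int  # 0 = practice
    shift: float | None  # percent; None for practice
    timeline: TempoTimeline | None  # None for practice
    true_steps: StepSeries
    trace: AccelTrace | None
    rpe: int
    song_id: int | None


@dataclass
class SimulatedDataset:
    """Full synthetic experiment: cohort profiles plus per-sequence records."""

    config: CohortConfig
    profiles: list[RunnerProfile]
    schedules: list[SessionSchedule]
    records: list[SequenceRecord]

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.profiles])

    def export(self, outdir, write_accel: bool = False) -> dict:
        """Write the dataset (CSV/JSON) and return the manifest dict.

        Step-series CSVs are always written; raw accelerometer CSVs only on
        request (they are bulky and reproducible from the manifest seed).
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "profiles.csv").write_text(self.profile_frame().to_csv(index=False))
        (outdir / "schedules.json").write_text(
            json.dumps([s.to_dict() for s in self.schedules], indent=1)
        )
        files = []
        seq_meta = []
        for rec in self.records:
            stem = f"{rec.participant_id}_seq{rec.sequence_index:02d}"
            steps_path = outdir / f"{stem}_steps.csv"
            rec.true_steps.to_frame().to_csv(steps_path, index=False, float_format="%.6f")
            files.append(steps_path.name)
            if write_accel and rec.trace is not None:
                accel_path = outdir / f"{stem}_accel.csv"
                rec.trace.to_frame().to_csv(accel_path, index=False, float_format="%.5f")
                files.append(accel_path.name)
            seq_meta.append(
                {
                    "participant_id": rec.participant_id,
                    "sequence_index": rec.sequence_index,
                    "shift": rec.shift,
                    "rpe": rec.rpe,
                    "song_id": rec.song_id,
                    "timeline": None
                    if rec.timeline is None
                    else {
                        "reference_bpm": rec.timeline.reference_bpm,
                        "shift": rec.timeline.shift,
                        "lap_bounds": list(rec.timeline.lap_bounds),
                        "ramp_s": rec.timeline.ramp_s,
                    },
                }
            )
        (outdir / "sequences.json").write_text(json.dumps(seq_meta, indent=1))
        manifest = {
            "seed": self.config.seed,
            "n_participants": self.config.n_participants,
            "n_sequences": len(self.records),
            "write_accel": bool(write_accel),
            "files": files,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest


def make_profiles(config: CohortConfig) -> list[RunnerProfile]:
    """Draw the cohort's runner profiles (deterministic in ``config.seed``)."""
    rng = np.random.default_rng(derive_seed(config.seed, "profiles"))
    profiles = []
    genders = ["female"] * config.n_female + ["male"] * config.n_male
    n = len(genders)
    trained = np.zeros(n, dtype=bool)
    trained[: int(round(config.training_fraction * n))] = True
    rng.shuffle(trained)
    for i, gender in enumerate(genders):
        mean_k = config.coupling_mean_female if gender == "female" else config.coupling_mean_male
        coupling = float(np.clip(rng.normal(mean_k, config.coupling_sd), 0.0, None))
        cadence = float(np.clip(rng.normal(config.cadence_mean, config.cadence_sd), 130.0, 200.0))
        speed = float(np.clip(rng.normal(config.speed_mean, config.speed_sd), 1.5, 6.0))
        profiles.append(
            RunnerProfile(
                id=f"P{i + 1:02d}",
                preferred_cadence=cadence,
                coupling=coupling,
                motor_noise_sd=config.motor_noise_sd,
                gender=gender,
                musical_training=bool(trained[i]),
                speed=speed,
            )
        )
    return profiles


def simulate_sequence(
    runner: RunnerProfile,
    shift: float | None,
    seed: int,
    ramp_s: float = 5.0,
    lap_distance_m: float = LAP_DISTANCE_M,
) -> tuple[StepSeries, TempoTimeline | None]:
    """Simulate one four-lap sequence, reproducing the adaptive protocol.

    Runs lap 1 silent, measures the reference cadence over its final 20 s,
    builds the tempo timeline for ``shift`` and re-runs the generator from
    the same seed — the lap-1 steps are bit-identical across the two passes
    because the coupling is inactive there, so the measured reference is
    consistent with the emitted steps.  ``shift=None`` gives the all-silent
    practice sequence.
    """
    lap_s = lap_distance_m / runner.speed
    durations = [lap_s] * LAPS_PER_SEQUENCE
    total = sum(durations)
    if shift is None:
        return simulate_steps(runner, None, seed, t_end=total), None
    pre = simulate_steps(runner, None, seed, t_end=durations[0])
    ref = reference_cadence(pre, lap1_end=durations[0])
    timeline = build_timeline(shift, ref, durations, ramp_duration=ramp_s)
    return simulate_steps(runner, timeline, seed), timeline


def simulate_cohort(
    config: CohortConfig,
    schedules: list[SessionSchedule] | None = None,
    library: StimulusLibrary | None = None,
    synth_traces: bool = True,
    accel_noise_sd: float = 0.5,
    sample_rate: float = 100.0,
    ramp_s: float = 5.0,
    lap_distance_m: float = LAP_DISTANCE_M,
    shifts=None,
) -> SimulatedDataset:
    """Simulate the full experiment: every participant, every sequence.

    Per participant this also emulates the music-selection stage: random
    BMRI-2 ratings over the packaged library, a top-20 playlist, and for
    each sequence the highest-rated song within 5 % of the reference
    cadence (nearest song as fallback when none qualifies).  RPE is drawn
    independently of entrainment, mid-scale, clipped to 6..20.
    """
    profiles = make_profiles(config)
    if schedules is None:
        kwargs = {} if shifts is None else {"shifts": tuple(shifts)}
        schedules = make_cohort_schedules(
            [p.id for p in profiles], seed=derive_seed(config.seed, "schedules"), **kwargs
        )
    sched_by_id = {s.participant_id: s for s in schedules}
    missing = [p.id for p in profiles if p.id not in sched_by_id]
    if missing:
        raise ValidationError(f"schedules missing for participants: {missing}")
    if library is None:
        library = packaged_library()

    records = []
    for profile in profiles:
        prng = np.random.default_rng(derive_seed(config.seed, "ratings", profile.id))
        ratings = [
            BmriRating(song_id=s.id, items=tuple(int(v) for v in prng.integers(1, 8, size=6)))
            for s in library.songs
        ]
        playlist = select_playlist(library, ratings, n=min(20, len(library)))
        rpe_rng = np.random.default_rng(derive_seed(config.seed, "rpe", profile.id))
        for seq in sched_by_id[profile.id].sequences:
            seq_seed = derive_seed(config.seed, "steps", profile.id, seq.index)
            steps, timeline = simulate_sequence(
                profile,
                seq.shift,
                seq_seed,
                ramp_s=ramp_s,
                lap_distance_m=lap_distance_m,
            )
            song_id = None
            if timeline is not None:
                try:
                    song_id = pick_song(playlist, timeline.reference_bpm).id
                except EligibilityError as err:
                    song_id = err.fallback.id
            trace = None
            if synth_traces:
                trace = synth_accel(
                    steps,
                    sample_rate=sample_rate,
                    noise_sd=accel_noise_sd,
                    seed=derive_seed(config.seed, "accel", profile.id, seq.index),
                )
            rpe = int(np.clip(round(rpe_rng.normal(config.rpe_mean, config.rpe_sd)), 6, 20))
            records.append(
                SequenceRecord(
                    participant_id=profile.id,
                    sequence_index=seq.index,
                    shift=seq.shift,
                    timeline=timeline,
                    true_steps=steps,
                    trace=trace,
                    rpe=rpe,
                    song_id=song_id,
                )
            )
    return SimulatedDataset(config=config, profiles=profiles, schedules=schedules, records=records)
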