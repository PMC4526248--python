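"""Step detection from tri-axial accelerometer traces and cadence estimation.

The detector works on the acceleration magnitude: remove the gravity
baseline (median), band-pass 1-5 Hz (covering 60-300 SPM step rates), and
pick peaks above an adaptive threshold (half the rolling 95th percentile)
with a refractory period of 60/220 s, which forbids rates above 220 SPM —
comfortably above the 130-200 SPM range of recreational runners.  Peak
times are refined by parabolic interpolation for sub-sample accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InsufficientDataError, ValidationError

#: band-pass edges for the step-frequency band, Hz
BAND_HZ = (1.0, 5.0)

#: refractory period between detected steps, seconds (220 SPM ceiling)
REFRACTORY_S = 60.0 / 220.0

#: adaptive threshold = this factor times the rolling 95th percentile
THRESHOLD_FRACTION = 0.5

#: window for the rolling percentile, seconds
PERCENTILE_WINDOW_S = 2.0


@dataclass
class StepSeries:
    """Ordered step-event times with per-step instantaneous cadence.

    ``inst_spm[i] = 60 / (t[i] - t[i-1])`` is assigned to the *later* step
    of each interval, so it is defined from the second step on (NaN for the
    first).
    """

    step_times: np.ndarray
    inst_spm: np.ndarray = field(init=False)

    def __post_init__(self):
        t = np.asarray(self.step_times, dtype=float)
        if t.ndim != 1:
            raise ValidationError("step_times must be 1-D")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValidationError("step_times must be strictly increasing")
        self.step_times = t
        spm = np.full(len(t), np.nan)
        if len(t) >= 2:
            spm[1:] = 60.0 / np.diff(t)
        self.inst_spm = spm

    def __len__(self) -> int:
        return len(self.step_times)

    def in_window(self, window) -> "StepSeries":
        """Steps with time in the half-open window [start, end)."""
        start, end = window
        mask = (self.step_times >= start) & (self.step_times < end)
        return StepSeries(step_times=self.step_times[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.step_times, "inst_spm": self.inst_spm})


def detect_steps(trace) -> StepSeries:
    """Detect step events in an :class:`~gaitsync.simulate.AccelTrace`.

    Returns peak times of the band-passed acceleration magnitude; see the
    module docstring for the pipeline.  Sub-sample peak positions come from
    a 3-point parabolic fit around each discrete maximum.

    Raises
    ------
    InsufficientDataError
        if the trace is shorter than 2 s.
    ValidationError
        if the sample rate is below 20 Hz.
    """
    fs = float(trace.sample_rate)
    if fs < 20.0:
        raise ValidationError(f"sample rate {fs} Hz below the 20 Hz minimum")
    samples = np.asarray(trace.samples, dtype=float)
    n = samples.shape[0]
    if n < 2.0 * fs:
        raise InsufficientDataError("trace shorter than 2 s")

    mag = np.sqrt(np.sum(samples**2, axis=1))
    mag = mag - np.median(mag)

    sos = signal.butter(2, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, mag)

    local = _rolling_percentile(filt, fs)
    # floor at a quarter of the global level: keeps the threshold adaptive to
    # slow amplitude drift yet immune to filter ringing in step-free stretches
    threshold = THRESHOLD_FRACTION * np.maximum(local, 0.25 * np.percentile(filt, 95))
    refractory = int(round(REFRACTORY_S * fs))
    peaks, _ = signal.find_peaks(filt, distance=max(refractory, 1))
    peaks = peaks[filt[peaks] > threshold[peaks]]

    times = trace.t0 + _refine_peaks(filt, peaks) / fs
    return StepSeries(step_times=times)


def _rolling_percentile(x: np.ndarray, fs: float, q: float = 95.0) -> np.ndarray:
    """Piecewise 95th percentile over ~2 s blocks, linearly interpolated.

    Block-wise evaluation keeps the adaptive threshold O(n) while tracking
    slow amplitude drift; detection is insensitive to the exact window.
    """
    block = max(int(round(PERCENTILE_WINDOW_S * fs)), 8)
    n = len(x)
    edges = np.arange(0, n, block)
    centers, values = [], []
    for s in edges:
        seg = x[s : s + block]
        centers.append(s + len(seg) / 2.0)
        values.append(np.percentile(seg, q))
    if len(values) == 1:
        return np.full(n, values[0])
    return np.interp(np.arange(n), centers, values)


def _refine_peaks(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Parabolic sub-sample refinement of discrete peak indices."""
    idx = peaks.astype(float)
    interior = (peaks > 0) & (peaks < len(x) - 1)
    p = peaks[interior]
    denom = x[p - 1] - 2.0 * x[p] + x[p + 1]
    ok = denom < 0
    shift = np.zeros(len(p))
    shift[ok] = 0.5 * (x[p - 1] - x[p + 1])[ok] / denom[ok]
    shift = np.clip(shift, -0.5, 0.5)
    idx[interior] = p + shift
    return idx


def mean_cadence(series: StepSeries, window) -> float:
    """Arithmetic mean of instantaneous SPM over steps in [start, end).

    Uses each step's own inter-step interval (assigned to the later step),
    so the first step inside the window contributes the interval that ends
    on it.

    Raises
    ------
    InsufficientDataError
        if fewer than 2 steps with defined cadence fall in the window.
    """
    start, end = window
    if end <= start:
        raise ValidationError("window end must exceed start")
    mask = (series.step_times >= start) & (series.step_times < end)
    vals = series.inst_spm[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise InsufficientDataError(
            f"fewer than 2 steps with cadence in window [{start:.2f}, {end:.2f})"
        )
    return float(np.mean(vals))
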