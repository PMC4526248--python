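"""Session protocol: condition set, per-participant schedules, tempo timelines.

A session is 12 four-lap sequences on a 200 m track.  The first sequence is
practice (no music).  Each of the remaining 11 sequences tests one tempo
condition: lap 1 silent (self-paced), lap 2 music tempo-matched to the
cadence measured over the final 20 s of lap 1, laps 3-4 music shifted by a
signed percentage of that reference tempo, reached through a short linear
ramp at the lap-3 onset.  The shifts span -3.00..+3.00 % — below the ~4 %
threshold at which an average listener notices a tempo change, so any
cadence adjustment is spontaneous rather than instructed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ValidationError

#: the 11 tempo-shift conditions, percent of the reference tempo
SHIFTS = (-3.0, -2.5, -2.0, -1.5, -1.0, 0.0, 1.0, 1.5, 2.0, 2.5, 3.0)

#: seconds of lap-1 tail used to measure the reference cadence
REFERENCE_WINDOW_S = 20.0

#: default linear ramp into the shifted tempo, seconds
RAMP_S = 5.0

LAPS_PER_SEQUENCE = 4
LAP_DISTANCE_M = 200.0


@dataclass(frozen=True)
class Condition:
    """One tempo-shift condition (percent change of the reference tempo)."""

    shift: float

    def __post_init__(self):
        if float(self.shift) not in {float(s) for s in SHIFTS}:
            raise ValidationError(f"shift {self.shift} not in the condition set {SHIFTS}")


@dataclass(frozen=True)
class SequenceDescriptor:
    """One four-lap sequence of a session."""

    index: int  # 0 = practice
    kind: str  # "practice" | "condition"
    shift: float | None  # percent; None for practice


@dataclass
class SessionSchedule:
    """Ordered sequences for one participant: practice + each condition once.

    ``condition_set`` defaults to the canonical 11 shifts; reduced sets are
    allowed for cut-down simulation runs.
    """

    participant_id: str
    order: tuple[float, ...]  # shifts in session order
    condition_set: tuple[float, ...] = SHIFTS

    def __post_init__(self):
        if sorted(self.order) != sorted(self.condition_set):
            raise ValidationError("schedule must contain each condition exactly once")

    @property
    def sequences(self) -> list[SequenceDescriptor]:
        seqs = [SequenceDescriptor(index=0, kind="practice", shift=None)]
        seqs += [
            SequenceDescriptor(index=i + 1, kind="condition", shift=s)
            for i, s in enumerate(self.order)
        ]
        return seqs

    def to_dict(self) -> dict:
        return {"participant_id": self.participant_id, "order": list(self.order)}


def make_cohort_schedules(
    participant_ids: list[str], seed: int, shifts: tuple[float, ...] = SHIFTS
) -> list[SessionSchedule]:
    """Seeded, pairwise-distinct condition orders, one schedule per participant.

    Orders are drawn by rejection sampling over uniform shuffles: simple,
    reproducible, and adequate for cohorts far below 11! permutations.
    """
    ids = [str(p) for p in participant_ids]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate participant ids")
    n_orders = math.factorial(len(shifts))
    if len(ids) > n_orders:
        raise ValidationError("more participants than distinct condition orders")
    rng = np.random.default_rng(seed)
    seen: set[tuple[float, ...]] = set()
    schedules = []
    for pid in ids:
        while True:
            order = tuple(rng.permutation(shifts).tolist())
            if order not in seen:
                seen.add(order)
                break
        schedules.append(
            SessionSchedule(participant_id=pid, order=order, condition_set=tuple(shifts))
        )
    return schedules


@dataclass
class TempoTimeline:
    """Piecewise BPM-vs-time for one four-lap sequence.

    Time 0 is the sequence (lap-1) start.  Lap 1 is silent; music starts at
    the lap-2 onset at ``reference_bpm``, ramps linearly over ``ramp_s``
    seconds from the lap-3 onset to the shifted tempo, then stays constant
    until the lap-4 end.
    """

    reference_bpm: float
    shift: float  # percent
    lap_bounds: tuple[float, ...]  # 5 ascending times, lap i spans [b[i], b[i+1])
    ramp_s: float = RAMP_S

    def __post_init__(self):
        if self.reference_bpm <= 0:
            raise ValidationError("reference_bpm must be positive")
        b = self.lap_bounds
        if len(b) != 5 or any(b[i + 1] <= b[i] for i in range(4)):
            raise ValidationError("lap_bounds must be 5 strictly ascending times")
        if self.ramp_s < 0 or self.ramp_s > b[4] - b[2]:
            raise ValidationError("ramp must fit inside laps 3-4")

    @property
    def shifted_bpm(self) -> float:
        return self.reference_bpm * (1.0 + self.shift / 100.0)

    @property
    def music_start(self) -> float:
        return self.lap_bounds[1]

    @property
    def end(self) -> float:
        return self.lap_bounds[4]

    def bpm_at(self, t):
        """BPM at time(s) ``t``; NaN where no music plays."""
        t = np.asarray(t, dtype=float)
        b = self.lap_bounds
        out = np.full(t.shape, np.nan)
        matched = (t >= b[1]) & (t < b[2])
        out[matched] = self.reference_bpm
        if self.ramp_s > 0:
            ramp = (t >= b[2]) & (t < b[2] + self.ramp_s)
            frac = (t[ramp] - b[2]) / self.ramp_s
            out[ramp] = self.reference_bpm + frac * (self.shifted_bpm - self.reference_bpm)
        after = (t >= b[2] + self.ramp_s) & (t < b[4])
        out[after] = self.shifted_bpm
        return out if out.ndim else float(out)

    def beat_times(self) -> np.ndarray:
        """Beat onsets over the music interval, first beat at the lap-2 onset.

        Generated by stepping one local period at a time; the tempo changes
        at most 3 % over a 5 s ramp, so the local-period approximation is
        exact to well under a millisecond per beat.
        """
        beats = []
        t = self.music_start
        while t < self.end:
            beats.append(t)
            bpm = self.bpm_at(t)
            if not np.isfinite(bpm) or bpm <= 0:
                break
            t += 60.0 / bpm
        return np.asarray(beats)


def build_timeline(
    condition,
    reference_bpm: float,
    lap_durations,
    ramp_duration: float = RAMP_S,
    t0: float = 0.0,
) -> TempoTimeline:
    """Assemble the four-lap tempo timeline for one condition.

    ``condition`` may be a :class:`Condition` or a bare shift percentage
    (floats outside the canonical 11-value set are allowed here so that
    simulation studies can probe arbitrary detunings).
    """
    shift = condition.shift if isinstance(condition, Condition) else float(condition)
    durations = [float(d) for d in lap_durations]
    if len(durations) != LAPS_PER_SEQUENCE or any(d <= 0 for d in durations):
        raise ValidationError("lap_durations must be 4 positive durations")
    bounds = tuple(float(t0) + x for x in itertools.accumulate([0.0] + durations))
    return TempoTimeline(
        reference_bpm=float(reference_bpm),
        shift=shift,
        lap_bounds=bounds,
        ramp_s=float(ramp_duration),
    )


def reference_cadence(step_series, lap1_end: float, window_s: float = REFERENCE_WINDOW_S) -> float:
    """Mean cadence (SPM) over the final ``window_s`` seconds of lap 1."""
    from .steps import mean_cadence  # local import avoids a cycle

    try:
        return mean_cadence(step_series, (lap1_end - window_s, lap1_end))
    except InsufficientDataError:
        raise InsufficientDataError(
            f"fewer than 2 steps in the {window_s:.0f} s reference window ending at {lap1_end:.1f} s"
        ) from None
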