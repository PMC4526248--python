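# Methods

## Scope

`gaitsync` implements the computational pipeline of a cadence-adaptive
music experiment: stimulus selection, session scheduling, a synthetic
runner/sensor generator, step detection, the two outcome measures and the
statistical battery. The original human dataset is not public; every
empirical number this package reports is computed from its own synthetic
cohort, and the tests are correspondingly split into *exact protocol
constants* and *properties of the model and estimators*.

## Protocol

A session is 12 four-lap sequences on a 200 m track; the first is a silent
practice set. In each remaining sequence, lap 1 is silent, lap 2 plays
music tempo-matched to the cadence measured over the final 20 s of lap 1,
and laps 3–4 play the same music shifted by one of
{−3.00, −2.50, −2.00, −1.50, −1.00, 0.00, +1.00, +1.50, +2.00, +2.50,
+3.00} % — below the ~4 % threshold at which tempo changes become
noticeable, so any adjustment is spontaneous. Condition orders are drawn
per participant by seeded rejection sampling over uniform shuffles,
pairwise distinct across the cohort; plain distinctness (not a Latin
square) is used, as nothing stronger is required of the design.

The tempo reaches its shifted value through a linear 5 s ramp at the lap-3
onset. Five seconds is also the head-trim of the analysis window, so ramp
tempos never enter scoring; the config validator warns if a longer ramp is
requested. Lap durations are self-paced: each runner's lap lasts
`200 m / speed`, with speed a per-runner parameter (default 2.78 m/s,
≈72 s per lap — an unhurried recreational pace).

Song selection mirrors the motivational-music stage: each runner rates all
117 library songs on the six-item BMRI-2 (1–7 Likert; scored as the item
sum, 6–42 — the instrument's standard aggregation, and monotonically
equivalent to the mean for ranking), the top 20 form a playlist, and each
sequence uses the highest-rated song within 5 % of the reference cadence
(window measured relative to the cadence, boundary inclusive; if no song
qualifies the nearest-tempo song is the documented fallback). The packaged
table retains its one out-of-range row (id 117, 210 BPM) flagged rather
than dropped, so the library count stays faithful to its source.

## Runner model

The gait generator is a stochastic circle map. With preferred period
`T_s = 60/SPM_pref`, beat period `T_b(t) = 60/BPM(t)` and relative phase
`φ` of the last footfall to the nearest beat (cycles, wrapped to
(−0.5, 0.5]):

```
interval = T_s − (K·T_b/2π)·sin(2πφ) + N(0, σ_motor)
```

A sinusoidal phase correction was chosen over a linear one because it
yields a finite entrainment basin: the noiseless map has a stable fixed
point iff the relative detuning `δ = T_s/T_b − 1` satisfies `|δ| < K/2π`.
Inside the basin the runner phase-locks (instantaneous cadence = tempo);
outside, the phase drifts with the characteristic intermittency of
quasiperiodic escape — near the edge the drift is slow and many steps
still fall within the 1 % entrainment criterion, so the score-vs-detuning
curve decays smoothly rather than dropping at the edge (this matters for
the basin estimator below). `K = 0` reduces exactly to uncoupled gait.
Intervals are floored at 0.2 s (300 SPM) to keep step times strictly
increasing under extreme noise draws.

Within a sequence the generator reproduces the protocol's adaptivity: lap 1
is simulated silent, the reference cadence is measured from its final 20 s,
the timeline is built from that reference, and the generator is re-run from
the same seed — lap-1 steps are bit-identical across the two passes because
coupling is inactive there, so the emitted data are self-consistent.

### Cohort defaults

| parameter | default | rationale |
|---|---|---|
| cohort | 9 female + 7 male | the study group's size and composition |
| coupling K | female 0.16, male 0.09 (SD 0.03) | free parameters producing the observed direction of the gender effect; half-widths ≈2.5 %/1.4 % detuning |
| preferred cadence | N(160, 10) SPM, clipped 130–200 | recreational-runner cadence range |
| motor noise σ | 10 ms per interval | plausible stride-interval variability; Gaussian, no long-range timekeeper structure |
| speed | N(2.78, 0.25) m/s | ~72 s self-paced laps |
| musical training | 62.5 % of cohort | the study group's composition |
| RPE | round(N(13, 2)), clipped 6–20 | mid-scale perceived exertion, drawn independently of entrainment — mirroring the null correlation the analysis probes |

All randomness derives from one master seed through
`sha256(seed, stage, participant, sequence)` (values < 2³¹), so stages are
reproducible independently and in any order.

### Accelerometer synthesis

Each step stamps a biphasic impulse on the vertical axis over a 9.81 m/s²
baseline: a Gaussian main lobe (σ = 20 ms, ≈80 ms overall width) peaked at
the step time, followed by a half-amplitude negative rebound. The main
lobe is symmetric so the zero-phase band-passed peak stays aligned with
the true step time. Default peak 8 m/s², white noise 0.5 m/s² on all three
axes (the peak is floored at 5× the noise SD); sampling 100 Hz. A sample
rate at or below twice the mean step rate raises an aliasing error.

What the generator does *not* emulate: ground-reaction biomechanics,
left/right foot asymmetry (the two ankle sensors are collapsed into one
step stream), sensor drift, transmission jitter, or any coupling of RPE to
the running task. Passing tests therefore validate the pipeline's
correctness and the model's qualitative behaviour, not quantitative
agreement with human data — the entrainment scores, for instance, sit
lower than a human control condition because a 10 ms interval noise against
a 1 % criterion caps the entrained fraction near 30 %.

## Step detection

Magnitude → median removal → order-2 Butterworth band-pass 1–5 Hz
(covering 60–300 SPM, applied forward-backward for zero phase) → peak
picking. The threshold is half the rolling 95th percentile (2 s blocks,
linearly interpolated), floored at a quarter of the trace-wide 95th
percentile so filter ringing in step-free stretches cannot trigger; both
terms scale with the signal, keeping detection amplitude-invariant. A
refractory period of 60/220 s forbids rates above 220 SPM. Peak times are
refined by 3-point parabolic interpolation for sub-sample accuracy
(≈15 ms worst-case error on clean traces; ≥99 % of steps matched within
50 ms at default noise). Windows are half-open `[start, end)` everywhere;
instantaneous cadence `60/(t_i − t_{i−1})` is assigned to the later step.

## Outcome measures

* **Cadence adaptation** `avg(SPM_TCL)/avg(SPM_TML)`: TCL window =
  laps 3–4 minus the first 5 s (ramp) and last 20 s (end-of-run behaviour);
  TML window = lap 2 minus its first 5 s, chosen for symmetry with the TCL
  head-trim since the averaging window for the matched lap is otherwise
  unspecified. Reported as ratio and percent change; percent change is the
  statistics default because it lives on the same scale as the tempo shift.
  For a noiseless strongly-coupled runner the measure equals the programmed
  shift to within 0.01 points at every condition (closed form: locked
  cadence equals the music tempo).
* **Entrainment score**: a step is entrained iff its instantaneous cadence
  is within 1 % of the concurrent tempo (inclusive; a 1e-12 epsilon keeps
  the boundary inclusive under float rounding). Instantaneous rather than
  windowed cadence implements the at-that-moment reading of the criterion.
  No phase-based index is computed — the criterion is deliberately
  tempo-based, capturing relative (not phase-locked) coordination.

## Statistics

Rank tests are implemented from their defining formulas, with scipy/
statsmodels/pingouin serving as independent cross-checks in the test suite:

* mean ranks on ties throughout;
* **Friedman**: tie-corrected χ² on within-row ranks, df = k−1;
* **Wilcoxon signed-rank**: zero differences dropped; statistic W⁺; Z with
  continuity correction; exact two-sided p by enumerating all 2ⁿ sign
  patterns for n ≤ 8 pairs, normal approximation above;
* **Mann–Whitney**: U = min(Uₓ, Uᵧ); Z tie-corrected *without* continuity
  correction (the convention of the major statistical packages for this
  test); exact p by enumerating all
  C(n₁+n₂, n₁) labelings when both groups have ≤ 8 observations;
* effect sizes r² = Z²/N;
* **Spearman**: Pearson on mean-tied ranks, two-tailed t-approximation;
* **KS normality**: D against a normal with estimated mean/SD; because the
  reference is fitted to the same data the p-value uses the Lilliefors
  distribution (plain KS would be anticonservative);
* **one-way RM-ANOVA** with a linear polynomial contrast: omnibus
  F(k−1, (n−1)(k−1)); the contrast uses centred shift values as
  coefficients with the subject-by-contrast interaction as its error term
  (df = n−1) and r² = SS_contrast/(SS_contrast+SS_error). The full
  11×2×2 mixed design with between-subject factors is out of scope; the
  gender effect is covered by the Mann–Whitney contrast on per-participant
  mean entrainment plus a descriptive per-gender adaptation slope.

The **basin analysis** compares each shifted condition's entrainment
against the 0 % control with Wilcoxon tests at the Bonferroni level
0.05/10 = 0.005, reporting per-condition medians, means ± SE, Z, p and
lower-than-control flags.

### Basin half-width estimation

The half-width estimator takes the cohort-mean score-vs-shift curve, finds
the half-maximum level (midway between curve max and min) and locates the
crossing on each side of the peak by linear interpolation. Because of the
intermittency noted above, the raw crossing systematically overshoots the
true edge — for the noiseless map the 50 % crossing sits ≈0.55–0.62 % of
detuning beyond the edge (computed from the dwell-time integral of the
drifting map against the 1 % criterion). The estimator therefore inverts
that map-derived relation to de-bias the raw crossing. On default cohorts
this recovers the cohort-mean K/2π within ±25 %.

## Problem sizes and numerical choices

The default run — 16 runners × 12 sequences, full accelerometer synthesis
and detection at 100 Hz (~5.5 M samples), metrics and the complete battery
— takes well under a minute on one CPU; the package's own budget for it is
five minutes. Beat times are generated by stepping one local period at a
time (the tempo moves ≤3 % across a 5 s ramp, keeping the approximation
below a millisecond per beat). Exact-enumeration p-values switch to normal
approximations above 8 observations per group. Degenerate inputs (zero
variance, all-zero differences, empty windows, flat score curves) raise
typed errors rather than returning silent NaNs.

## Known limitations

* The coupling constants, noise magnitudes and the sinusoidal correction
  form are stipulated, not estimated from human data; only directions and
  qualitative shapes (linear adaptation trend, basin at extreme shifts,
  female > male entrainment) are expected to transfer.
* Entrainment levels depend strongly on the motor-noise-to-criterion ratio;
  absolute scores are not comparable to human values.
* The basin estimator assumes a single dominant basin and a reasonably
  smooth cohort-mean curve; per-runner curves from single sequences are too
  noisy for reliable recovery.
* Step detection is single-stream; no gait-event subtypes, no left/right
  fusion.
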