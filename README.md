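# gaitsync

Simulation and analysis of **spontaneous entrainment of running cadence to
music tempo**.

Recreational runners listening to music whose tempo sits close to their step
rate tend to lock their footfalls to the beat — without being asked to and
without noticing. Because step rate modulates lower-limb joint loading,
imperceptibly tempo-shifted music is a candidate tool for gait retraining.
`gaitsync` packages the full computational side of such an experiment for
movement scientists who want to prototype, power or re-analyze
cadence-adaptive music protocols:

* a rated 117-song stimulus library (130–200 BPM) with BMRI-2 motivational
  scoring and tempo-matched song selection;
* the session protocol: 12 four-lap sequences on a 200 m track, the first a
  silent practice set, the remaining 11 each testing one tempo shift of
  −3.00…+3.00 % applied after a tempo-matched lap;
* a synthetic-runner generator (phase-correction gait model + 100 Hz
  ankle-accelerometer synthesis) standing in for the non-public human data;
* accelerometer step detection and the two outcome measures — cadence
  adaptation and the tempo-entrainment score;
* the nonparametric statistical battery with the entrainment-basin analysis.

## The model

A runner with preferred step period `T_s = 60/SPM_pref` is a stochastic
circle map driven by the beat. At each step, the relative phase φ to the
nearest beat (in cycles, wrapped to (−0.5, 0.5]) corrects the next interval:

```
interval = T_s − (K·T_b/2π)·sin(2πφ) + ε,   ε ~ N(0, σ_motor)
```

with `T_b` the local beat period and `K ≥ 0` the coupling gain. The
noiseless map phase-locks exactly when the relative detuning
`|T_s/T_b − 1|` is below `K/2π` — an Arnold tongue whose half-width is the
runner's *entrainment basin*. Outcomes follow the experimental definitions:

* **cadence adaptation** = `avg(SPM_TCL) / avg(SPM_TML)` — mean cadence in
  the tempo-changed laps (first 5 s and last 20 s trimmed) over the
  tempo-matched lap — reported as a ratio and as percent change;
* **tempo-entrainment score** = percentage of steps whose instantaneous
  cadence is within 1 % (inclusive) of the concurrent music tempo.

## Worked example

```python
import gaitsync as gs

runner = gs.RunnerProfile(id="R1", preferred_cadence=160.0, coupling=0.13,
                          motor_noise_sd=0.010, gender="female")
steps, timeline = gs.simulate_sequence(runner, shift=2.0, seed=7)
trace = gs.synth_accel(steps, noise_sd=0.5, seed=8)
detected = gs.detect_steps(trace)
ratio, pct, ent = gs.sequence_metrics(detected, timeline)
print(f"reference tempo : {timeline.reference_bpm:.1f} BPM -> shifted {timeline.shifted_bpm:.1f} BPM")
print(f"steps detected  : {len(detected)} (true: {len(steps)})")
print(f"cadence adaptation: {pct:+.2f} %  (ratio {ratio:.4f})")
print(f"entrainment score : {ent:.1f} %")
print(f"basin half-width  : {runner.basin_halfwidth_pct:.2f} % detuning")
```

prints

```
reference tempo : 160.7 BPM -> shifted 163.9 BPM
steps detected  : 774 (true: 774)
cadence adaptation: +1.02 %  (ratio 1.0102)
entrainment score : 27.6 %
basin half-width  : 2.07 % detuning
```

The runner's cadence in the silent lap (160.7 SPM) sets the music tempo of
lap 2; laps 3–4 ramp it up by 2 %. With `K = 0.13` the +2 % detuning sits
at the edge of this runner's ~2.07 % basin: the cadence follows the music
about half-way (+1.02 %), and with 10 ms motor noise roughly a quarter of
the steps count as tempo-entrained.

The same pipeline runs from the shell:

```bash
gaitsync run-all --seed 1 --out runs/demo          # full 16-runner cohort
gaitsync run-all --seed 4 --out runs/tiny --participants 1 --conditions "0"
```

A run directory contains the exported dataset, `metrics.csv` (one row per
participant × condition), `summary.csv`, `stats_report.json` (RM-ANOVA with
linear contrast, Friedman, Wilcoxon-vs-control basin tests at the
Bonferroni .005 level, Mann–Whitney gender/training contrasts, Spearman
entrainment–RPE) and a log; reruns with the same config are byte-identical.

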