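# pursuitlab

Simulation and analysis pipeline for a smooth-pursuit / time-to-contact
psychophysics paradigm: two Gaussian-windowed random-dot objects 6 deg apart,
one moving at 3/4/5 deg/s along a step-ramp, both disappearing 500 ms after
motion onset, with the observer pressing a button at the estimated moment of
contact. The package covers the full computational chain on synthetic data:

- **`pursuitlab.design`** — stimulus geometry, step-ramp trajectory (100-ms
  recross), first/second-order motion descriptors, trial timeline, and the
  randomly interleaved 9-cell x 20-repetition session builder.
- **`pursuitlab.simulate`** — ground-truth-annotated 1-kHz eye traces
  (latency-delayed pursuit onset, linear acceleration to a gain-scaled steady
  state, post-occlusion exponential decay, Poisson catch-up saccades as
  minimum-jerk steps, blink NaN spans) and button responses from a
  perceived-speed extrapolation model with scalar timing and motor noise.
  Population defaults live in `data/observer_defaults.yaml`.
- **`pursuitlab.preprocess`** — central-difference differentiation, 80-tap
  30-Hz FIR low-pass (zero-phase by default, NaN-span aware), saccade
  detection (|v| >= 30 deg/s OR |a| >= 1000 deg/s^2), desaccading to NaN,
  blink detection, trial QC (±2-deg fixation excursion, saccades to the
  stationary object, blinks in the presentation period), trace averaging.
- **`pursuitlab.pursuit`** — pretrial baseline, pursuit onset (> 3 SD above
  baseline, sustained), latency, initial acceleration (first 100 ms),
  steady-state velocity, saccade rate.
- **`pursuitlab.ttc`** — constant/absolute/variable error, reaction time
  from occlusion onset, per-cell aggregation, and the previous-trial (n-1)
  velocity table.
- **`pursuitlab.stats`** — two-way repeated-measures ANOVA with partial
  eta-squared (optional Greenhouse-Geisser), Bonferroni pairwise follow-ups,
  and the within-subjects correlation coefficient.
- **`pursuitlab.io` / `config` / `pipeline` / `cli`** — CSV/YAML/JSON
  formats, the `RunConfig` object holding every tunable analysis decision,
  and the end-to-end driver.

## CLI

All verbs accept `--config <yaml>` and `--seed <int>`:

```sh
pursuitlab run --seed 1 --out results/run1          # full pipeline
pursuitlab simulate --seed 1 --out data/ds1         # write a dataset
pursuitlab qc --dataset data/ds1 --out qc.csv       # preprocessing + QC only
pursuitlab metrics --seed 1 --out results/metrics
pursuitlab stats --seed 1 --out results/stats
pursuitlab report --results results/run1            # plain-text summary
```

`pursuitlab run` writes the QC/events/metrics/results/aggregates tables, the
statistics tables (CSV + `stats.json`), the resolved `config.yaml`, and a
`run.log` with the config hash, seed, and exclusion counts per reason.
Identical config + seed reproduces identical outputs.

## Conventions

Time is in ms with t = 0 at motion onset; positions in degrees, rightward
positive; the gazed object sits at -3 deg. Analysis-window choices that the
paradigm description leaves open (baseline window, steady-state window,
onset sustain, desaccade padding, capture radius) are explicit fields of
`RunConfig` with their defaults documented in the dataclasses.
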