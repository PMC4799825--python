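# hdrisk

Risk prediction for malaise during hemodialysis sessions, built as a fully
tested pipeline:

- **`hdrisk.cohort`** — synthetic cohort generator. Sessions carry a 9-point
  vitals grid (SBP, DBP, HR, weight at 0–240 min in 30-min steps),
  prescription fields and the outcome label. Vitals are drawn from
  per-patient normals with per-timepoint class mean shifts for symptomatic
  sessions, and the cross-parameter correlation structure (weight↔vitals per
  class, SBP↔DBP, near-unit weight autocorrelation) is induced through a
  triangular transform. `verify_cohort_stats` recovers the class-difference
  t-tests and per-class Pearson correlations.
- **`hdrisk.features`** — engineered inputs: interdialytic weight gain
  ((start weight − previous end weight) / dry weight), the piecewise SBP
  criticality indicator in [0, 1], and the 13-column feature rows for the
  two classifier stages (RF1: T0 + T2 vitals, criticality at T1/T2;
  RF2: T0 + T6 vitals, criticality at T5/T6). RF2 labels count only
  last-hour-onset sessions as positive.
- **`hdrisk.oversample`** — minority-class balancing with correlated
  Gaussian noise: KS normality screen, standard-normal generation,
  correlation induction (`u' = u·√(1−ρ²) + v·ρ`, generalized to a Cholesky
  factor of the repaired correlation matrix), and `mu + k·sigma·z` moment
  restoration with noise scale `k`.
- **`hdrisk.classify`** — dual random forests under leave-one-out
  cross-validation with per-fold oversampling (no train/test leakage:
  the held-out session enters neither training nor the oversampler's
  estimates). Scores are symptomatic-class vote fractions; the fused score
  is the mean of the two stage scores.
- **`hdrisk.evaluate`** — ROC sweep, trapezoidal AUC (≡ pairwise-ranking
  probability), Hanley–McNeil standard error, AUC-comparison z-test,
  Youden-index cutoff, accuracy/sensitivity/specificity at cutoff, and the
  noise-scale (`k`) robustness sweep.
- **`hdrisk.io` / `hdrisk.cli`** — CSV session tables, YAML configuration,
  and the seeded end-to-end driver.

## CLI

```sh
hdrisk simulate  --seed 1 --out run/                  # cohort CSVs
hdrisk featurize --stage rf1 --sessions run/sessions.csv \
                 --timepoints run/timepoints.csv --out run/
hdrisk oversample --sessions run/sessions.csv \
                  --timepoints run/timepoints.csv --n AUTO --out run/over
hdrisk train-eval --sessions run/sessions.csv \
                  --timepoints run/timepoints.csv --seed 1 --out run/
hdrisk report    --scores run/scores.csv --out run/
hdrisk run-all   --seed 1 --out run/                  # full pipeline
```

`run-all` writes `sessions.csv`/`timepoints.csv`, per-session LOOCV
`scores.csv`, a `report.csv` (AUC ± SE, Youden cutoff, accuracy,
sensitivity, specificity for each stage and the fused score) and a
`manifest.json` recording config, derived stage seeds and library versions.
All commands accept `--config FILE` (YAML) and are fully deterministic
given `--seed`.

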