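# sensefuse

Cross-study generalizability analysis for passive mobile-sensing
mental-health symptom prediction.

`sensefuse` harmonizes two heterogeneous longitudinal mobile-sensing
studies (a clinical-style study with a 10-item 0–3 EMA battery on a fixed
Mon/Wed/Fri cadence, and a student-style study with raw-derived sensing,
different response scales and an irregular EMA schedule) into one
feature/outcome schema, runs leave-one-subject-out (LOSO) experiments
comparing combined vs. single-study training, and quantifies when combining
helps via the Proxy-A distance and a clustered nonparametric sensitivity
analysis. A synthetic two-study generator stands in for the original
datasets, so the whole pipeline is testable offline; real data in the same
delimited-text schemas can be supplied instead.

## Pipeline

1. **`sensefuse.synth`** — paired synthetic studies: heavy-tailed hourly
   sensing streams (log-normal durations/distance, negative-binomial
   counts), configurable behavior→symptom links (shared or opposed across
   studies), ordinal 0–3 outcomes with controllable severe-category
   priors, per-study EMA schedules and day-level missingness. The paper
   publishes no generative model; all distributional choices are labeled
   stand-ins with parameters exposed in the config.
2. **`sensefuse.harmonize`** — day + four 6-hour epoch features per sensing
   variable (8 variables × 5 features + 3 day-level sleep features = 43),
   a 19-hour coverage rule for raw-derived studies, EMA normalization onto
   the common 0–3 scale with severity labeling, and trailing 3-day window
   alignment with a 44th missing-day counter.
3. **`sensefuse.training`** — the LOSO-CV engine: single-study vs. combined
   training pools, k-nearest-neighbor personalization, SMOTE oversampling,
   Huber-loss gradient-boosted tree regressors over the declared
   432-point hyperparameter grid, plus constant-mean baselines.
4. **`sensefuse.domain_distance`** — Proxy-A distance `2(1 − 2ε)` between
   each held-out subject and each candidate training pool (linear SVM,
   stratified cross-validated error, majority side subsampled).
5. **`sensefuse.stats`** — per-subject MAE, paired ΔMAE deltas, one-sided
   Wilcoxon signed-rank tests (standard and cluster-adjusted), rank-biserial
   and Cramér's V effect sizes, Benjamini–Hochberg correction, severity
   classification metrics, two-sample distribution comparisons, and the
   GEE/LMM regression of ΔMAE on ΔPAD.
6. **`sensefuse.pipeline` / `sensefuse.cli`** — end-to-end orchestration
   with YAML config, CSV artifacts and a reproducibility manifest.

## CLI

```bash
# full experiment from a config file
sensefuse all --config experiment.yaml --out results/

# or stage by stage
sensefuse simulate  --config experiment.yaml --out data/
sensefuse harmonize --config experiment.yaml \
    --sensing data/sensing.csv --ema data/ema.csv --out data/instances.csv
sensefuse run-loso  --instances data/instances.csv --outcome stress \
    --grid grid.yaml --modes single,combined --seed 1 --out results/
sensefuse pad       --instances data/instances.csv --outcome stress \
    --seed 1 --out results/pad.csv
sensefuse stats     --predictions results/predictions_stress.csv \
    --pad results/pad.csv --out results/
```

Example `experiment.yaml`:

```yaml
seed: 1
items: [sleep, stress]
min_ema: 30
study_a: {n_subjects: 20, n_days: 180, severe_frac: 0.22}
study_b: {n_subjects: 20, n_days: 70, loc_shift: {act_still: 15.0},
          missing_day_rate: 0.1}
# omit `grid` for the full 432-configuration grid
grid: {learning_rates: [0.01, 0.1], n_trees: [20, 100], depths: [3],
       smote: [true, false], ks: [5, null]}
```

`ks: null` means "all neighbors" (no personalization).

## Data schemas (delimited text)

- sensing: `subject, study, date, variable, hour, value` (hour empty for
  day-level sleep variables)
- EMA: `subject, study, timestamp, item, raw_value`
- instances: `subject, study, timestamp, item, <44 feature columns>,
  outcome, severe`
- predictions: `subject, study, item, mode, learning_rate, n_trees, depth,
  smote, k, timestamp, y_true, y_pred`
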