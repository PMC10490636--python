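# insole-weight

Personalized human body-weight estimation from smart shoe-insole sensor
streams: adaptive bias correction for zero-inflated pressure channels,
dynamic-windowing feature extraction with alpha-trimmed-mean aggregation,
per-participant regression models, and a five-metric evaluation protocol.
Because the original study recordings are private, the package ships a
seeded synthetic-cohort generator that reproduces the statistical structure
the pipeline depends on (weight-proportional forces, participant-specific
load shares, per-recording sensor dropouts, noise, drift, sway, and
disturbance bursts) in the same on-disk layout.

## Data model

A dataset is a directory of participant folders, each with activity
subfolders (`sitting` / `standing` / `walking`) holding 51-column delimited
text recordings named `{w}lbs_{activity}{iteration}.txt` (no suffix means
iteration 1), plus a `ground_truth.csv` (or `.xlsx`) mapping participants
to body weight in lbs. Each recording carries a timestamp and, per foot,
16 pressure channels, total force, a 3-axis accelerometer and gyroscope,
and center-of-pressure x/y.

The pipeline per participant:

1. **Adaptive bias** (`adaptive_bias`): per feature, the smallest strictly
   positive sample at the heaviest carried weight (falling back to lighter
   weights) scales an additive correction that grows linearly with the
   weight-class index. ZRAB corrects only exact-zero readings; FAB corrects
   every sample.
2. **Dynamic windowing + trimming** (`windowed_features`): window geometry
   is derived from the recording length and two user parameters; each
   window collapses to one row via the alpha-trimmed mean (`alpha=0` is the
   mean, `alpha=50` the median). Six synthesized aggregates extend the 34
   raw channels to 40 model features.
3. **Personalized model** (`personalized_model`): one regressor per
   participant, trained on designated iterations with a stratified 80/20
   split and 5-fold CV, tested on a held-out iteration, and scored with
   MAE / MSE / RMSE / R^2 / MAPE plus a per-carried-weight MAE breakdown.

## CLI

```bash
insole-weight simulate --config examples/cohort.yaml --seed 1 --out data/
insole-weight run      --config examples/cohort.yaml --seed 1 --out reports/
insole-weight ablate   --config examples/cohort.yaml --seed 1 --out ablation/
```

`simulate` writes a synthetic cohort (plus `manifest.json` with the config
hash), `run` executes the full pipeline and writes per-participant and
cohort reports (CSV/JSON), and `ablate` sweeps bias mode x sample length x
trim alpha into one CSV row per grid cell. See `examples/cohort.yaml` for
all configuration keys.

## Tests and acceptance report

```bash
python -m pytest -q                 # full suite (a few minutes)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance criteria: worked examples
on the published per-participant metric table, trimmed-mean limit
properties, seeded end-to-end trend checks (bias mode, sample length, trim
alpha), parameter recovery, and brute-force oracle equivalence.
`scripts/acceptance.py` recomputes the numeric acceptance targets through
the package's aggregation operations and writes them as JSON.
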