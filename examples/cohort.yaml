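# Synthetic cohort + pipeline configuration.
# Used by: insole-weight simulate|run|ablate --config examples/cohort.yaml

simulate:
  n_balanced: 1          # near-uniform load shares, no sensor dropouts
  n_unbalanced: 6        # skewed load shares + per-recording dropouts
  weight_class: [0, 2, 3, 5, 7, 9, 11, 13]   # carried dumbbell weights (lbs)
  n_iterations: 2
  sampling_rate: 50      # Hz (25 or 50)
  duration_per_weight: 20.0   # seconds per recording
  noise_sd: 0.02         # relative i.i.d. sensor noise
  drift_sd: 0.001        # per-step sd of the re-zeroed baseline walk
  drift_reset: 60        # samples between baseline re-zeroing
  outlier_prob: 0.0      # per-sample whole-row outliers
  outlier_scale: 3.0
  burst_prob: 0.0        # transient posture-shift bursts
  burst_len: 30
  burst_scale: 0.6
  sway_amp: 0.0          # postural-sway load oscillation
  sway_persist: 4
  sway_jitter: 0.2
  sway_balance: 0.5
  unbalanced_dropout: 0.25    # per-sensor, per-recording dropout probability
  body_weight_range: [110.0, 220.0]

run:
  dataset: simulated_dataset
  # ground_truth: simulated_dataset/ground_truth.csv   # default
  activities: [standing]
  bias_mode: fab         # none | zrab | fab
  l_samples: 100
  olap_init: 0.2
  alpha: 15
  train_iterations: [1]
  test_iteration: 2
  learner: extra_trees   # extra_trees | lightgbm | catboost
  n_estimators: 100
  cv_folds: 5
  train_fraction: 0.8

ablate:
  bias_modes: [none, zrab, fab]
  l_samples: [25, 50, 100]
  alphas: [0, 10, 15, 25, 50]
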