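# Full-pipeline configuration for `sparsepk run-all`.
# Every stage derives its own seed from the root seed below.
seed: 42
outdir: sparsepk_run

simulate:
  n_subjects: 300
  tvcl: 15.90        # typical clearance, L/h
  v: 2182.0          # apparent volume, L
  ka: 0.5            # absorption rate constant, 1/h
  omega_cl: 0.3      # between-subject SD on log clearance
  sigma_add: 10.0    # additive residual SD, ng/mL
  cl_covariate_ratios:
    SMOK: 1.5        # smokers clear the drug 1.5x faster

split:
  train_frac: 0.70
sequence:
  time_steps: 2
scaler:
  scope: train       # or "pooled"

poppk:
  candidates:
    - [SMOK, categorical]
    - [SEX, categorical]
    - [RACE_B, categorical]

hyperopt:
  sampler: tpe       # or "random"
  n_trials: 20
  pruning: true
  # Optionally narrow the search space, e.g.:
  # space: {lstm_nodes: [8, 64], ann_nodes: [8, 128]}

# To skip tuning and train a fixed architecture instead:
# skip: [hyperopt]
# architecture:
#   n_lstm_blocks: 1
#   lstm_nodes: 8
#   n_dense_blocks: 2
#   dense_nodes: [88, 184]
# train:
#   learning_rate: 0.000125
#   epochs: 69

pimp:
  n_reps: 10
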