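# Default model configuration. The stage-2 hyperparameters are package
# defaults chosen for smooth tabular release data; all are overridable per
# call or by supplying a modified copy of this file.
stage1:
  regularization: 0.5
  # "inverse": the value is the sklearn C (smaller = stronger penalty);
  # "penalty": the value is the penalty weight lambda, C = 1/lambda.
  regularization_convention: inverse
  solver: lbfgs
  standardize: true
  folds: 10
  threshold: 0.5
stage2:
  folds: 5
  # "global": one global stage-1 out-of-fold pass feeds every outer fold;
  # "nested": stage 1 is refit inside each outer training fold (strict,
  # leakage-free stacking).
  stacking: global
  algorithms:
    lr: {}
    svr:
      kernel: rbf
      C: 1.0
      epsilon: 0.02
      gamma: scale
    dt:
      max_depth: 8
      min_samples_leaf: 5
    rf:
      n_estimators: 500
      min_samples_leaf: 2
      n_jobs: 1
    xgb:
      n_estimators: 500
      max_depth: 6
      learning_rate: 0.05
      subsample: 0.9
      colsample_bytree: 0.9
      tree_method: hist
      n_jobs: 1
    lgbm:
      n_estimators: 500
      max_depth: 6
      learning_rate: 0.05
      subsample: 0.9
      colsample_bytree: 0.9
      n_jobs: 1
      verbose: -1
validation:
  n_repeats: 30
  test_fraction: 0.2
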