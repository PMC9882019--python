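# Default pipeline configuration. All numeric defaults live here, none in
# code. The shipped task geometry (default_task.yaml) is used unless
# task_config points elsewhere.
seed: 1
output_dir: results/run
task_config: null

calibration:
  skip: true          # geometry ships pre-calibrated; set false to recalibrate
  target_gap: 0.01    # ideal-Bayes minus maximum-likelihood generative accuracy
  budget: 60000       # Monte-Carlo trials per calibration evaluation

cohort:
  policy: logistic
  variants: [dimensionality, boundary, volume, robustness]
  n_participants: 6       # per variant (the human study used ~50)
  n_trials: 120           # per participant (the human study used ~500)
  beta_mean: [0.0, 1.0, 4.66, 1.12, 0.23, 2.21]
  beta_scale: [0.1, 0.1, 0.96, 0.10, 0.12, 0.12]

simulate:
  n_observers: 20
  n_trials: 200

sampler:
  chains: 4
  n_warmup: 600
  n_draws: 600
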