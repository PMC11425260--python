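# Full-pipeline run configuration (caflux run --config configs/example_run.yaml)
seed: 7
cohort_mode: parametric
alpha: 0.05
generator:
  n_cells_per_condition: 30
  duration: 180.0        # s, 3-minute recordings
  dt: 0.05               # s, 20 Hz sampling
  noise_sd: 0.2          # fluorescence units
  cell_variability: 0.15 # lognormal CV of per-cell parameters
featurizer:
  baseline_quantile: 0.10
  kappa: 3.0
  min_separation: 2.0
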