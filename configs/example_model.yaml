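# Model parameter overrides (caflux simulate/stability --config configs/example_model.yaml)
params:
  beta: 2.0    # 1/s   cytosol -> extracellular efflux
  alpha: 1.3   # 1/s   maximum CICR flux
  gamma: 2.0   # uM/s  plasma-membrane influx
  n: 4         #       Hill coefficient
  delta: 1.3   # uM    half-occupation concentration
  k: 0.01      # 1/s   ER leak
  k1: 2.0      # 1/s   SERCA uptake
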