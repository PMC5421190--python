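{
  "sigma1": 1.0,
  "sigma2": 0.5,
  "tau0": 3.0,
  "c": 1.0,
  "n_modes": 3,
  "omega_range": [
    0.3,
    2.0
  ],
  "omega_samples": 60
}
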