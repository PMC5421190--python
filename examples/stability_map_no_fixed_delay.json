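{
  "sigma1": 0.3333333333333333,
  "sigma2": 0.25,
  "tau0": 0.0,
  "c": 0.8,
  "kJ1_range": [
    -2.0,
    2.0
  ],
  "kJ2_range": [
    -2.0,
    2.0
  ],
  "grid": 5,
  "n_max": 3
}
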