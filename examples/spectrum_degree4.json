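{
  "sigma1": 0.2222222222222222,
  "sigma2": 0.16666666666666666,
  "tau0": 3.0,
  "c": 0.8,
  "kJ1": 29.5,
  "kJ2": -51.38,
  "n_max": 5
}
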