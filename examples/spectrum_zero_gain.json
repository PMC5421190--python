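{
  "sigma1": 1.0,
  "sigma2": 0.5,
  "tau0": 3.0,
  "c": 1.0,
  "kJ1": 0.0,
  "kJ2": 0.0,
  "n_max": 3
}
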