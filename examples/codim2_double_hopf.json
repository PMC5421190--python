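{
  "sigma1": 1.0,
  "sigma2": 0.5,
  "tau0": 3.0,
  "c": 1.0,
  "alpha": 1.0,
  "beta": 4.0,
  "delta": 0.1
}
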