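{
  "rho0": 0.5,
  "rho1": 0.5,
  "omega0": 0.861,
  "omega1": 0.609,
  "a1": [
    -1.0,
    0.3
  ],
  "a2": [
    -2.0,
    -0.2
  ],
  "b1": [
    -1.0,
    0.1
  ],
  "b2": [
    -0.5,
    0.2
  ],
  "b3": [
    -2.0,
    -0.4
  ]
}
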