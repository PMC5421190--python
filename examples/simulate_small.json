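{
  "alpha": 1.0,
  "beta": 4.0,
  "delta": 0.1,
  "J1": 1.0,
  "J2": -2.0,
  "sigma1": 1.0,
  "sigma2": 0.5,
  "tau0": 3.0,
  "c": 1.0,
  "dt": 0.05,
  "t_final": 5.0,
  "mesh_level": 2,
  "initial": [
    "random",
    0.001
  ],
  "seed": 0,
  "save_every": 10,
  "snapshot_indices": [
    0
  ]
}
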