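{
  "allow_zero_diffusion": true,
  "grid": {
    "M": 41,
    "T_end": 8.0,
    "dT": 0.0001,
    "snapshot_times": []
  },
  "initial": {
    "Z": 1,
    "h_amp": 0.0,
    "n_amp": 0.02,
    "n_mean": 1.0,
    "theta_amp": 0.0,
    "theta_mean": 0.6
  },
  "mode": "simulate",
  "params": {
    "D": 0.0,
    "N": 100.0,
    "R": 1.0,
    "chi": 0.4,
    "lam": 1.0,
    "mu_p0": 0.0,
    "mu_s0": 0.0,
    "tau0": 1.0,
    "xi": 1.0
  }
}
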