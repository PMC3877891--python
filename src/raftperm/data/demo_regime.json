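{
  "kd": 5.1,
  "target_ic50": 10.2,
  "m": 4,
  "site_density": 1.0,
  "k_olig": 1.0,
  "theta_sigma": 0.6
}
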