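{
  "air": {
    "density_g_cm3": 0.001205,
    "z_over_a": 0.4992
  },
  "lung": {
    "density_g_cm3": 0.26,
    "z_over_a": 0.55
  },
  "adipose": {
    "density_g_cm3": 0.95,
    "z_over_a": 0.5558
  },
  "soft_tissue": {
    "density_g_cm3": 1.06,
    "z_over_a": 0.55
  },
  "water": {
    "density_g_cm3": 1.0,
    "z_over_a": 0.5551
  },
  "bone": {
    "density_g_cm3": 1.92,
    "z_over_a": 0.5148
  },
  "aluminium": {
    "density_g_cm3": 2.699,
    "z_over_a": 0.4818
  },
  "pmma": {
    "density_g_cm3": 1.19,
    "z_over_a": 0.5394
  }
}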