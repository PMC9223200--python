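{
  "growth": {"mu_N_max": 0.175, "K_N": 0.0133},
  "yield": {"family": "quad_exp", "a": 10.0, "b": 13.0, "N_dagger": 0.35},
  "second_step": {"k": 2.17, "beta": 1.622, "mu_S_max": 0.393, "K_S": 19.2, "K_E": 71.9},
  "meta": {
    "name": "experimental-2022",
    "description": "Maintenance model calibrated simultaneously on laboratory fermentations (three batches, shared conditions, N0 in {0.170, 0.283, 0.567} g/L).",
    "notes": "SYNTHETIC yield values: the experimental yield fit was published only as a figure, so the quad_exp parameters here are plausible stand-ins (chosen to give deltaX(0.567) ~ 4.2 g/L); growth and second-step values are the reported simultaneous fit."
  }
}
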