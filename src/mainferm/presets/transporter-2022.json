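{
  "growth": {"mu_N_max": 0.103, "K_N": 0.0381},
  "yield": {"family": "linear_smoothed", "a": 7.55, "b": 0.808, "N_dagger": 0.176},
  "second_step": {"k": 2.17, "beta": 2.41, "mu_S_max": 0.197, "K_S": 21.1, "K_E": 72.7},
  "meta": {
    "name": "transporter-2022",
    "description": "Maintenance model calibrated against simulations of a hexose-transporter fermentation model; isothermal 24 C, N0 validity [0.071, 0.57] g/L.",
    "notes": "Linear-smoothed yield: a is the asymptotic yield slope (g/g), b the endpoint-line offset (g/L)."
  }
}
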