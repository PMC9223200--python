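{
  "growth": {"mu_N_max": 0.27, "K_N": 0.00952},
  "yield": {"family": "quad_exp", "a": 15.1, "b": 15.2, "N_dagger": 0.465},
  "second_step": {"k": 2.17, "beta": 3.22, "mu_S_max": 0.197, "K_S": 17.6, "K_E": 36.4},
  "meta": {
    "name": "sofa-2022",
    "description": "Maintenance model calibrated against simulations of a logistic decision-support fermentation model; isothermal 24 C, N0 validity [0.071, 0.57] g/L.",
    "notes": "Quad-exp yield: the reported units tag a as g/L and b as unitless, but dimensional consistency of y = b - 2aN requires b in g/g and a in g/g per g/L; interpreted accordingly."
  }
}
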