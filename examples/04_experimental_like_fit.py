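"""Simultaneous calibration on experimental-like data (no nitrogen signal).

Laboratory fermentations typically measure a handful of biomass points and
dense CO2 / CO2-rate series, but never nitrogen over time — so growth
kinetics cannot be identified separately and all six kinetic parameters
are fitted at once, after calibrating the yield function on endpoints.
"""

import numpy as np

import mainferm as mf

ps = mf.load_preset("experimental-2022")

# 8 biomass points, dense CO2, mild noise — the realistic design
noise = mf.NoiseModel(cv={"X": 0.05, "CO2": 0.01, "dCO2dt": 0.01},
                      n_X_points=8, seed=0)
chronicles, _ = mf.gen_chronicles(ps, noise=noise)
endpoints, _ = mf.gen_endpoints(ps, list(np.linspace(0.071, 0.567, 12)))

fit = mf.fit_all(chronicles, endpoints, family="quad_exp",
                 N_dagger=ps.yield_fn.N_dagger, use_biomass=True,
                 init_growth=mf.GrowthParams(0.2, 0.02),
                 init_second=mf.SecondStepParams(2.17, 1.6, 0.4, 25.0, 60.0))

gp = fit.params["growth"]
sp = fit.params["second_step"]
print(f"mu_N_max = {gp.mu_N_max:.4f} 1/h   (true {ps.growth.mu_N_max})")
print(f"K_N      = {gp.K_N:.5f} g/L   (true {ps.growth.K_N})")
print(f"beta     = {sp.beta:.3f}       (true {ps.second_step.beta})")
print(f"mu_S_max = {sp.mu_S_max:.4f} 1/h  (true {ps.second_step.mu_S_max})")
print(f"K_S      = {sp.K_S:.2f} g/L    (true {ps.second_step.K_S})")
print(f"K_E      = {sp.K_E:.2f} g/L    (true {ps.second_step.K_E})")
print("normalized RMSE per variable:",
      {k: f"{v:.3f}" for k, v in fit.extra["rmse_per_variable"].items()})
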