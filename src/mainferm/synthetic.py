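"""Synthetic fermentation datasets with known ground truth.

Generates chronicles and endpoint datasets by simulating the maintenance
model under the standard batch operating conditions (X(0) = 0.02 g/L,
S(0) = 200 g/L, 350 h horizon, N(0) in [0.071, 0.57] g/L), optionally
corrupted by multiplicative lognormal measurement noise and subsampled to
an experimental-like design (a handful of biomass points, dense CO2).

These datasets stand in for the outputs of the two literature fermentation
models (the transporter model and the logistic decision-support model) and
for the laboratory measurements: each of those is represented here by the
maintenance model under the corresponding fitted preset.  The surrogate
stance is recorded in every truth record so downstream analyses cannot
misattribute the data.  Noise touches only the observations; the paired
truth record always carries the exact generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import EndpointDataset
from .io import ParameterSet, params_to_dict
from .simulator import Chronicle, SimulationConfig, State, simulate

__all__ = ["NoiseModel", "ScenarioGrid", "gen_chronicles", "gen_endpoints",
           "N0_VALIDITY", "STANDARD_N0"]

#: interval of initial nitrogen over which the presets were calibrated (g/L)
N0_VALIDITY = (0.071, 0.57)

#: the three scenario values used for trajectory comparisons (g/L)
STANDARD_N0 = (0.170, 0.283, 0.567)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model for synthetic observations.

    cv : coefficient of variation of the multiplicative lognormal noise,
    either one scalar for all variables or a per-variable mapping.
    n_X_points : when set, biomass is observed only at this many log-spaced
    times (the experimental design: ~8 biomass samples against dense CO2).
    seed : RNG seed, fixed per dataset for reproducibility.
    """

    cv: float | dict = 0.0
    n_X_points: Optional[int] = None
    seed: int = 0

    def cv_for(self, var: str) -> float:
        c = self.cv.get(var, 0.0) if isinstance(self.cv, dict) else self.cv
        if c < 0:
            raise ValueError("noise CV must be >= 0")
        return float(c)

    def describe(self) -> dict:
        return {"cv": self.cv, "n_X_points": self.n_X_points, "seed": self.seed}


@dataclass(frozen=True)
class ScenarioGrid:
    """Initial-nitrogen scenarios sharing the standard operating conditions."""

    N0_values: tuple = STANDARD_N0
    X0: float = 0.02
    S0: float = 200.0
    t_end: float = 350.0

    def __post_init__(self) -> None:
        if not len(self.N0_values):
            raise ValueError("need at least one N0 value")
        object.__setattr__(self, "N0_values", tuple(float(v) for v in self.N0_values))

    def init_state(self, n0: float) -> State:
        return State(X=self.X0, N=n0, S=self.S0)

    def out_of_validity(self) -> list[float]:
        lo, hi = N0_VALIDITY
        return [v for v in self.N0_values if not lo <= v <= hi]


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise with the requested CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def _truth_record(preset: ParameterSet, noise: NoiseModel, **extra) -> dict:
    rec = {
        "params": params_to_dict(preset),
        "noise": noise.describe(),
        "surrogate_note": (
            "data generated by the maintenance/variable-yield model under "
            f"preset {preset.name!r}; NOT by the literature model this preset "
            "was originally calibrated against"),
    }
    rec.update(extra)
    return rec


def gen_chronicles(preset: ParameterSet,
                   grid: ScenarioGrid = ScenarioGrid(),
                   noise: NoiseModel = NoiseModel(),
                   cfg: Optional[SimulationConfig] = None,
                   ) -> tuple[list[Chronicle], dict]:
    """Simulate one chronicle per scenario and apply the measurement model.

    Returns the (possibly noisy, possibly subsampled) chronicles plus a
    truth record holding the exact generating parameters and settings.
    With zero CV and no subsampling the chronicles are the simulator output
    unchanged.
    """
    cfg = cfg or SimulationConfig(t_end=grid.t_end)
    rng = np.random.default_rng(noise.seed)
    out = []
    for n0 in grid.N0_values:
        ch = simulate(grid.init_state(n0), preset.growth, preset.yield_fn,
                      preset.second_step, cfg,
                      meta={"preset": preset.name, "seed": noise.seed})
        if noise.n_X_points is not None:
            # biomass observed only at a few log-spaced times; keep the grid
            # and blank the unobserved biomass entries
            t_obs = np.geomspace(5.0, ch.time[-1], noise.n_X_points)
            idx = np.unique(np.searchsorted(ch.time, t_obs))
            idx = np.clip(idx, 0, len(ch) - 1)
            X = np.full_like(ch.X, np.nan)
            X[idx] = ch.X[idx]
            ch.X = X
            ch.meta["X_observed_at"] = ch.time[idx].tolist()
        for var in ("X", "N", "S", "E", "CO2", "dCO2dt"):
            col = getattr(ch, var)
            if col is None:
                continue
            cv = noise.cv_for(var)
            if cv > 0:
                setattr(ch, var, col * _lognormal_factor(rng, cv, col.shape))
        out.append(ch)
    truth = _truth_record(
        preset, noise,
        scenarios={"N0_values": list(grid.N0_values), "X0": grid.X0,
                   "S0": grid.S0, "t_end": grid.t_end},
        warnings=[f"N0={v:g} outside validity interval {N0_VALIDITY}"
                  for v in grid.out_of_validity()],
    )
    return out, truth


def gen_endpoints(preset: ParameterSet,
                  N0_values: Sequence[float],
                  noise: NoiseModel = NoiseModel(),
                  ) -> tuple[EndpointDataset, dict]:
    """Endpoint pairs (N0, deltaX) from the closed-form curve f.

    For an exhausted fermentation deltaX equals f(N0) exactly, so endpoints
    are taken from the yield family's closed form rather than a simulation;
    noise is applied multiplicatively to deltaX.  N0 values outside the
    preset's validity interval are flagged in the truth record (the yield
    below 0.071 g/L was never observed).
    """
    n0 = np.asarray(list(N0_values), float)
    rng = np.random.default_rng(noise.seed)
    lo, hi = N0_VALIDITY
    warn = [f"N0={v:g} outside validity interval {N0_VALIDITY}"
            for v in n0 if not lo <= v <= hi]
    if n0.size:
        delta = preset.yield_fn.f(n0) * _lognormal_factor(
            rng, noise.cv_for("deltaX"), n0.shape)
        ds = EndpointDataset(N0=n0, deltaX=np.atleast_1d(delta))
    else:
        ds = EndpointDataset(N0=n0, deltaX=np.array([]))
    truth = _truth_record(preset, noise, N0_values=n0.tolist(), warnings=warn)
    return ds, truth
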