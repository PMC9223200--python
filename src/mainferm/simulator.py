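"""Batch fermentation simulator.

Integrates the two-step model: yeast growth on nitrogen (Contois kinetics
with maintenance, or equivalently a variable yield), coupled with sugar
conversion into ethanol and CO2 (Monod kinetics with ethanol inhibition):

    dX/dt   = mu_N(N, X) * X
    dN/dt   = -mu_N * X / y(N)                      (variable-yield form)
            = -mu_N * X / Y - alpha(N) * mu_N * X   (maintenance form, Y=y(0))
    dE/dt   = dCO2/dt = (mu_N + beta * nu_E(E) * mu_S(S)) * X
    dS/dt   = -k * dCO2/dt

Both formulations are algebraically identical; exposing both lets the
equivalence be verified numerically.  Ethanol and CO2 are integrated as
separate states even though their derivatives coincide, so that restarts
with E(0) != CO2(0) remain well-posed.

Default operating conditions are the batch wine-fermentation setting used
throughout: X(0) = 0.02 g/L, S(0) = 200 g/L, E(0) = CO2(0) = 0, a 350 h
horizon, and initial nitrogen N(0) in [0.071, 0.57] g/L as the scenario
variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (
    GrowthParams,
    SecondStepParams,
    State,
    YieldFunction,
    contois_rate,
    ethanol_inhibition,
    monod_rate,
)

__all__ = [
    "SimulationConfig",
    "Chronicle",
    "rhs",
    "simulate",
    "endpoint",
    "co2_peak",
    "DEFAULT_INIT",
    "FORMULATIONS",
]

FORMULATIONS = ("variable_yield", "maintenance")

#: standard batch operating conditions (N0 is the scenario variable)
DEFAULT_INIT = State(X=0.02, N=0.0, S=200.0, E=0.0, CO2=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    t_end : horizon (h); dt : output grid spacing (h); rtol/atol :
    integrator tolerances; eps_N : nitrogen floor below which the
    fermentation is declared exhausted (g/L).
    """

    t_end: float = 350.0
    dt: float = 1.0
    formulation: str = "variable_yield"
    rtol: float = 1e-8
    atol: float = 1e-10
    eps_N: float = 1e-6

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.dt <= 0 or self.rtol <= 0 or self.atol <= 0:
            raise ValueError("dt and tolerances must be > 0")
        if self.eps_N < 0:
            raise ValueError("eps_N must be >= 0")
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation!r}; "
                             f"expected one of {FORMULATIONS}")


_COLUMNS = ("X", "N", "S", "E", "CO2", "dCO2dt")


@dataclass
class Chronicle:
    """Time-indexed fermentation trajectory.

    Any subset of the state columns may be present (experimental chronicles
    typically carry only X, CO2 and dCO2/dt); absent columns are ``None``.
    ``meta`` records provenance: initial conditions, preset name, seed.
    """

    time: np.ndarray
    X: Optional[np.ndarray] = None
    N: Optional[np.ndarray] = None
    S: Optional[np.ndarray] = None
    E: Optional[np.ndarray] = None
    CO2: Optional[np.ndarray] = None
    dCO2dt: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for c in _COLUMNS:
            v = getattr(self, c)
            if v is not None:
                v = np.asarray(v, float)
                if v.shape != self.time.shape:
                    raise ValueError(f"column {c} length mismatch with time")
                setattr(self, c, v)
        if all(getattr(self, c) is None for c in _COLUMNS):
            raise ValueError("chronicle needs at least one variable column")

    def __len__(self) -> int:
        return self.time.size

    @property
    def columns(self) -> list[str]:
        return [c for c in _COLUMNS if getattr(self, c) is not None]

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time}
        data.update({c: getattr(self, c) for c in self.columns})
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "Chronicle":
        if "time" not in df.columns:
            raise ValueError("missing 'time' column")
        kw = {c: df[c].to_numpy(float) for c in _COLUMNS if c in df.columns}
        return cls(time=df["time"].to_numpy(float), meta=meta or {}, **kw)

    def initial_state(self) -> State:
        """State at the first grid point (requires X, N, S columns)."""
        for c in ("X", "N", "S"):
            if getattr(self, c) is None:
                raise ValueError(f"cannot build initial state: column {c} missing")
        return State(X=self.X[0], N=self.N[0], S=self.S[0],
                     E=self.E[0] if self.E is not None else 0.0,
                     CO2=self.CO2[0] if self.CO2 is not None else 0.0)


def rhs(state: State,
        gp: GrowthParams,
        yf: YieldFunction,
        sp: SecondStepParams,
        formulation: str = "variable_yield") -> np.ndarray:
    """Time derivative of (X, N, S, E, CO2) at one state.

    Concentrations are clipped at zero inside the rate laws so that small
    integrator undershoots cannot produce spurious negative-rate feedback;
    in particular both dN/dt forms vanish at N = 0, so nitrogen cannot be
    driven negative (the failure mode of a constant maintenance term).
    """
    if formulation not in FORMULATIONS:
        raise ValueError(f"unknown formulation {formulation!r}")
    X = max(state.X, 0.0)
    N = max(state.N, 0.0)
    S = max(state.S, 0.0)
    E = max(state.E, 0.0)

    mu = contois_rate(N, X, gp)
    dX = mu * X
    if formulation == "variable_yield":
        dN = -mu * X / float(yf.y(N))
    else:
        Y = float(yf.y(0.0))
        dN = -mu * X / Y - float(yf.alpha(N)) * mu * X
    dCO2 = (mu + sp.beta * ethanol_inhibition(E, sp) * monod_rate(S, sp)) * X
    dS = -sp.k * dCO2
    return np.array([dX, dN, dS, dCO2, dCO2])  # order: X, N, S, dE(=dCO2), dCO2


def _make_rhs(gp, yf, sp, formulation):
    """Float-only RHS closure: integration hot path, no dataclass churn."""
    mu_max, K_N = gp.mu_N_max, gp.K_N
    k, beta, mu_s_max, K_S, K_E = sp.k, sp.beta, sp.mu_S_max, sp.K_S, sp.K_E
    y_s = yf.y_scalar
    variable = formulation == "variable_yield"
    Y0 = y_s(0.0)

    def f(t, v):
        X = v[0] if v[0] > 0.0 else 0.0
        N = v[1] if v[1] > 0.0 else 0.0
        S = v[2] if v[2] > 0.0 else 0.0
        E = v[3] if v[3] > 0.0 else 0.0
        mu = mu_max * N / (N + K_N * X) if N > 0.0 else 0.0
        dX = mu * X
        if variable:
            dN = -mu * X / y_s(N)
        else:
            yn = y_s(N)
            dN = -mu * X / Y0 - (1.0 / yn - 1.0 / Y0) * mu * X
        dCO2 = (mu + beta * mu_s_max * S / ((K_S + S) * (1.0 + E / K_E))) * X
        return (dX, dN, -k * dCO2, dCO2, dCO2)

    return f


def simulate(init: State,
             gp: GrowthParams,
             yf: YieldFunction,
             sp: SecondStepParams,
             cfg: SimulationConfig = SimulationConfig(),
             meta: dict | None = None,
             times: np.ndarray | None = None) -> Chronicle:
    """Integrate the batch model and return a full chronicle.

    Uses LSODA (adaptive step, automatic stiff/non-stiff switching): the
    system is mildly stiff near nitrogen exhaustion.  The reported CO2
    production rate is evaluated exactly from the right-hand side at each
    output time rather than by differencing.  ``times`` overrides the
    uniform output grid (used when matching observed sampling times).
    """
    if times is not None:
        t_grid = np.asarray(times, float)
        if t_grid.size == 0:
            raise ValueError("times must be non-empty")
        t_end = float(t_grid[-1])
    else:
        t_grid = np.arange(0.0, cfg.t_end + 0.5 * cfg.dt, cfg.dt)
        if t_grid[-1] < cfg.t_end:
            t_grid = np.append(t_grid, cfg.t_end)
        t_end = cfg.t_end
    sol = solve_ivp(
        _make_rhs(gp, yf, sp, cfg.formulation), (0.0, t_end),
        init.as_array(), t_eval=t_grid,
        method="LSODA", rtol=cfg.rtol, atol=cfg.atol,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(
            f"integration failed at t = {last_t:g} h: {sol.message}")
    ys = np.clip(sol.y, 0.0, None)
    X, N, S, E = ys[0], ys[1], ys[2], ys[3]
    mu = np.where(N > 0, gp.mu_N_max * N / (N + gp.K_N * X), 0.0)
    dco2 = (mu + sp.beta * sp.mu_S_max * S
            / ((sp.K_S + S) * (1.0 + E / sp.K_E))) * X
    m = dict(meta or {})
    m.setdefault("N0", float(init.N))
    m.setdefault("X0", float(init.X))
    m.setdefault("S0", float(init.S))
    m.setdefault("formulation", cfg.formulation)
    return Chronicle(time=sol.t, X=ys[0], N=ys[1], S=ys[2], E=ys[3],
                     CO2=ys[4], dCO2dt=dco2, meta=m)


def endpoint(init: State,
             gp: GrowthParams,
             yf: YieldFunction,
             sp: SecondStepParams,
             cfg: SimulationConfig = SimulationConfig()) -> tuple[float, float, bool]:
    """Run to the horizon and report (N0, deltaX, exhausted).

    deltaX = X(t_end) - X(0) equals the endpoint curve f(N0) whenever the
    nitrogen is exhausted at the horizon (the change-of-variable identity
    behind the whole yield-calibration strategy).
    """
    ch = simulate(init, gp, yf, sp, cfg)
    delta_x = float(ch.X[-1] - ch.X[0])
    thresh = max(cfg.eps_N, 1e-3 * init.N)
    exhausted = bool(ch.N[-1] < thresh)
    return float(init.N), delta_x, exhausted


def co2_peak(ch: Chronicle) -> tuple[float, float]:
    """Time and height of the CO2 production-rate peak (ties -> earliest)."""
    if ch.dCO2dt is None:
        raise ValueError("chronicle has no dCO2dt column")
    if len(ch) == 0:
        raise ValueError("empty chronicle")
    i = int(np.argmax(ch.dCO2dt))
    return float(ch.time[i]), float(ch.dCO2dt[i])


def with_n0(n0: float, init: State = DEFAULT_INIT) -> State:
    """Standard initial state with the scenario nitrogen value."""
    return replace(init, N=float(n0))
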