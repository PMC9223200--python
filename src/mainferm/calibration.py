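"""Staged identification of the maintenance / variable-yield model.

The identifiability structure of the model dictates a three-stage procedure:

1. **Growth kinetics.**  The Contois parameters (mu_N_max, K_N) are fitted
   on pairs (r, dlogX/dt) with r = N/X, either by nonlinear least squares
   on mu(r) = mu_N_max * r / (K_N + r) or by a linear regression on the
   reciprocal form 1/rate = 1/mu_N_max + (K_N/mu_N_max) / r.  The
   linearization is convenient for inspection but weights small rates
   heavily, so it degrades under heteroscedastic noise.

2. **Yield function.**  Independently of the kinetics, the endpoint identity
   X(inf) - X(0) = f(N(0)) lets the cumulative yield curve f be fitted by
   linear regression on endpoint data (N0, deltaX); the variable yield is
   y = f', from which the maintenance factor alpha follows.  The smoothing
   threshold N_dagger is not identifiable from endpoints above it; it can be
   fixed, or grid-searched against reference trajectories.

3. **Sugar pathway.**  With growth and yield frozen, the CO2-production
   parameters (beta, mu_S_max, K_S, K_E) are fitted by nonlinear least
   squares on CO2 chronicles, each variable normalized by its maximum over
   the dataset; the stoichiometric yield k is kept at its literature value
   (2.17 g sugar per g CO2).

When nitrogen is not measured (the experimental situation), stages 1 and 3
collapse into a simultaneous fit of all six kinetic parameters on the CO2
(optionally plus biomass) chronicles, with the yield still calibrated first
from endpoints.

All nonlinear fits use Levenberg-Marquardt with finite-difference Jacobians
on log-parameters (positivity by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    GrowthParams,
    SecondStepParams,
    State,
    YieldConstant,
    YieldFunction,
    YieldLinearSmoothed,
    YieldQuadExp,
)
from .simulator import Chronicle, SimulationConfig, simulate

__all__ = [
    "GrowthRateDataset",
    "EndpointDataset",
    "FitResult",
    "growth_rate_data_from_chronicle",
    "fit_contois",
    "fit_yield",
    "fit_second_step",
    "fit_all",
    "metrics",
    "K_LITERATURE",
]

#: literature value of the sugar-per-CO2 stoichiometric yield (g/g)
K_LITERATURE = 2.17


@dataclass
class GrowthRateDataset:
    """Pairs of nitrogen-to-biomass ratio r = N/X (g/g) and specific growth
    rate dlogX/dt (1/h)."""

    r: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        self.rate = np.asarray(self.rate, float)
        if self.r.shape != self.rate.shape:
            raise ValueError("r and rate must have the same length")
        if np.any(self.r < 0) or not np.all(np.isfinite(self.rate)):
            raise ValueError("r must be >= 0 and rates finite")

    def __len__(self) -> int:
        return self.r.size


@dataclass
class EndpointDataset:
    """Endpoint records (N0, deltaX = X(T) - X(0)), optionally weighted."""

    N0: np.ndarray
    deltaX: np.ndarray
    weight: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.N0 = np.asarray(self.N0, float)
        self.deltaX = np.asarray(self.deltaX, float)
        if self.N0.shape != self.deltaX.shape:
            raise ValueError("N0 and deltaX must have the same length")
        if self.N0.size and (np.any(self.N0 <= 0) or np.any(self.deltaX <= 0)):
            raise ValueError("N0 and deltaX must be strictly positive")
        if self.weight is not None:
            self.weight = np.asarray(self.weight, float)
            if self.weight.shape != self.N0.shape or np.any(self.weight <= 0):
                raise ValueError("weights must be positive, one per record")

    def __len__(self) -> int:
        return self.N0.size

    @property
    def w(self) -> np.ndarray:
        return np.ones_like(self.N0) if self.weight is None else self.weight


@dataclass
class FitResult:
    """Outcome of a calibration stage.

    ``rse`` is the residual standard error of a linear regression
    (sqrt(RSS/(n-p))); ``rmse`` the root-mean-square error (denominator n)
    on the scale stated by the fitting routine (normalized data for the
    trajectory fits).  ``fixed`` maps parameter names to whether they were
    held fixed.
    """

    params: object
    rse: Optional[float] = None
    rmse: Optional[float] = None
    success: bool = True
    message: str = ""
    nfev: int = 0
    fixed: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage 1: growth kinetics
# ---------------------------------------------------------------------------

def growth_rate_data_from_chronicle(ch: Chronicle) -> GrowthRateDataset:
    """Extract (N/X, dlogX/dt) pairs from a chronicle.

    The specific growth rate is estimated by central finite differences of
    log X at interior grid points (one-sided at the ends), paired with the
    ratio N/X at the same time.
    """
    if ch.X is None or ch.N is None:
        raise ValueError("chronicle must have X and N columns")
    if len(ch) < 3:
        raise ValueError("need at least 3 time points")
    t, X, N = ch.time, ch.X, ch.N
    if np.any(X <= 0):
        raise ValueError("X must be strictly positive to take log")
    logX = np.log(X)
    rate = np.empty_like(logX)
    rate[1:-1] = (logX[2:] - logX[:-2]) / (t[2:] - t[:-2])
    rate[0] = (logX[1] - logX[0]) / (t[1] - t[0])
    rate[-1] = (logX[-1] - logX[-2]) / (t[-1] - t[-2])
    return GrowthRateDataset(r=N / X, rate=rate)


def _contois_mu(r: np.ndarray, mu_max: float, K: float) -> np.ndarray:
    return mu_max * r / (K + r)


def _linearized_contois(data: GrowthRateDataset,
                        rate_floor: float = 1e-3) -> tuple[float, float]:
    # The reciprocal transform is singular at rate -> 0: the post-exhaustion
    # points (r ~ 0, rate ~ 0) carry no kinetic information but acquire
    # unbounded leverage after inversion, so the regression is restricted to
    # the growth phase (rate above a small fraction of the peak rate).
    mask = (data.r > 0) & (data.rate > rate_floor * data.rate.max())
    r, rate = data.r[mask], data.rate[mask]
    if np.unique(r).size < 2:
        raise ValueError("need at least 2 distinct positive r values")
    # OLS of 1/rate on 1/r
    A = np.column_stack([np.ones_like(r), 1.0 / r])
    coef, *_ = np.linalg.lstsq(A, 1.0 / rate, rcond=None)
    intercept, slope = coef
    if intercept <= 0:
        raise ValueError(
            f"linearized fit gave non-positive intercept ({intercept:g}); "
            "data incompatible with a saturating ratio-dependent law")
    return 1.0 / intercept, slope / intercept  # mu_N_max, K_N


def fit_contois(data: GrowthRateDataset, method: str = "nls") -> FitResult:
    """Fit the Contois parameters on growth-rate data.

    method="nls" minimizes sum (mu(r_i) - rate_i)^2 by Levenberg-Marquardt;
    method="linearized" regresses 1/rate on 1/r and back-transforms.  Both
    report the RMSE on the rate scale; the nls route is preferred on noisy
    data since the reciprocal transform inflates the weight of small rates.
    """
    if method not in ("nls", "linearized"):
        raise ValueError(f"unknown method {method!r}")
    if np.unique(data.r).size < 2:
        raise ValueError("need at least 2 distinct r values (non-identifiable)")

    if method == "linearized":
        mu_max, K = _linearized_contois(data)
        gp = GrowthParams(mu_max, K)
        resid = _contois_mu(data.r, mu_max, K) - data.rate
        # RSE of the underlying linear regression (reciprocal scale)
        mask = (data.r > 0) & (data.rate > 1e-3 * data.rate.max())
        lin_res = (1.0 / _contois_mu(data.r[mask], mu_max, K)
                   - 1.0 / data.rate[mask])
        n = mask.sum()
        rse = float(np.sqrt(np.sum(lin_res**2) / max(n - 2, 1)))
        return FitResult(params=gp, rse=rse,
                         rmse=float(np.sqrt(np.mean(resid**2))),
                         message="linear regression on reciprocal form")

    try:
        x0 = np.array(_linearized_contois(data))
    except ValueError:
        x0 = np.array([max(data.rate.max(), 1e-3) * 1.2,
                       max(np.median(data.r), 1e-3)])
    res = least_squares(
        lambda p: _contois_mu(data.r, np.exp(p[0]), np.exp(p[1])) - data.rate,
        np.log(np.maximum(x0, 1e-12)), method="lm", xtol=1e-12, ftol=1e-12,
        max_nfev=3000)
    mu_max, K = np.exp(res.x)
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    if not res.success:
        raise RuntimeError(
            f"Contois fit did not converge: {res.message}; best iterate "
            f"mu_N_max={mu_max:g}, K_N={K:g}, rmse={rmse:g}")
    return FitResult(params=GrowthParams(mu_max, K), rmse=rmse,
                     nfev=res.nfev, message=res.message)


# ---------------------------------------------------------------------------
# stage 2: yield function from endpoints
# ---------------------------------------------------------------------------

def _wls(A: np.ndarray, yv: np.ndarray, w: np.ndarray,
         dof: int) -> tuple[np.ndarray, float]:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], yv * sw, rcond=None)
    resid = yv - A @ coef
    n = yv.size
    rse = float(np.sqrt(np.sum(w * resid**2) / max(n - dof, 1)))
    return coef, rse


def _fit_yield_fixed(data: EndpointDataset, family: str,
                     N_dagger: Optional[float]) -> FitResult:
    w = data.w
    if family == "constant":
        if len(data) < 1:
            raise ValueError("need at least 1 endpoint")
        A = data.N0[:, None]
        coef, rse = _wls(A, data.deltaX, w, dof=1)
        return FitResult(params=YieldConstant(float(coef[0])), rse=rse,
                         message="through-origin regression")

    if N_dagger is None:
        raise ValueError(f"family {family!r} requires N_dagger")

    if family == "linear_smoothed":
        mask = data.N0 >= N_dagger
        if mask.sum() < 2:
            raise ValueError(
                "need >= 2 endpoints with N0 >= N_dagger for the linear branch")
        A = np.column_stack([data.N0[mask], np.ones(mask.sum())])
        coef, rse = _wls(A, data.deltaX[mask], w[mask], dof=2)
        a, b = float(coef[0]), float(coef[1])
        if a <= 0 or b <= 0:
            raise ValueError(
                f"linear-branch regression gave a={a:g}, b={b:g}; the family "
                "requires both positive (b ~ 0 indicates a constant yield)")
        return FitResult(params=YieldLinearSmoothed(a, b, float(N_dagger)),
                         rse=rse, fixed={"N_dagger": True},
                         message="OLS of deltaX on N0, N0 >= N_dagger")

    if family == "quad_exp":
        mask = data.N0 < N_dagger
        if mask.sum() < 3:
            raise ValueError(
                "need >= 3 endpoints with N0 < N_dagger for the quadratic branch")
        A = np.column_stack([data.N0[mask], data.N0[mask] ** 2])
        coef, rse = _wls(A, data.deltaX[mask], w[mask], dof=2)
        b, a = float(coef[0]), float(-coef[1])
        if b - 2.0 * a * N_dagger <= 0:
            raise ValueError(
                f"fitted quad_exp family invalid: b - 2*a*N_dagger = "
                f"{b - 2.0 * a * N_dagger:g} <= 0")
        return FitResult(params=YieldQuadExp(a, b, float(N_dagger)),
                         rse=rse, fixed={"N_dagger": True},
                         message="origin-constrained OLS of deltaX on (N0, N0^2)")

    raise ValueError(f"unknown yield family {family!r}")


def fit_yield(data: EndpointDataset,
              family: str = "linear_smoothed",
              N_dagger: float | str | None = None,
              auto_grid: Optional[Sequence[float]] = None,
              growth: Optional[GrowthParams] = None,
              reference: Optional[Sequence[Chronicle]] = None,
              second_step: Optional[SecondStepParams] = None) -> FitResult:
    """Fit the cumulative yield curve f on endpoint data (N0, deltaX).

    linear_smoothed: OLS of deltaX on N0 over the endpoints above the
    threshold gives (a, b).  quad_exp: origin-constrained OLS of deltaX on
    (N0, N0^2) below the threshold gives (b, -a).  constant: through-origin
    regression gives Y.  With ``N_dagger="auto"``, the threshold is
    grid-searched (default: 21 points spanning the N0 range) minimizing the
    summed normalized RMSE of the X and N trajectories against reference
    chronicles simulated with ``growth`` — the threshold only shapes the
    transient, so endpoints alone cannot pin it down.
    """
    if N_dagger != "auto":
        return _fit_yield_fixed(data, family,
                                None if N_dagger is None else float(N_dagger))

    if growth is None or not reference:
        raise ValueError("N_dagger='auto' requires growth params and "
                         "reference chronicles")
    if auto_grid is None:
        auto_grid = np.linspace(data.N0.min(), data.N0.max(), 21)
    sp = second_step or SecondStepParams(K_LITERATURE, 1.0, 0.1, 20.0, 50.0)
    best: tuple[float, FitResult] | None = None
    trace = []
    for nd in auto_grid:
        try:
            fr = _fit_yield_fixed(data, family, float(nd))
        except ValueError:
            continue
        score = 0.0
        try:
            for ref in reference:
                sim = simulate(ref.initial_state(), growth, fr.params, sp,
                               times=ref.time)
                for var in ("X", "N"):
                    obs = getattr(ref, var)
                    if obs is None:
                        continue
                    m = np.isfinite(obs)
                    scale = np.nanmax(np.abs(obs))
                    score += float(np.sqrt(np.mean(
                        ((getattr(sim, var)[m] - obs[m]) / scale) ** 2)))
        except RuntimeError:
            continue
        trace.append((float(nd), score))
        if best is None or score < best[0]:
            best = (score, fr)
    if best is None:
        raise ValueError("no N_dagger candidate produced a valid fit")
    best[1].extra["auto_grid"] = trace
    best[1].fixed["N_dagger"] = False
    best[1].message += "; N_dagger grid-searched against reference trajectories"
    return best[1]


# ---------------------------------------------------------------------------
# stage 3: sugar-pathway parameters on CO2 chronicles
# ---------------------------------------------------------------------------

def _dataset_norms(chronicles: Sequence[Chronicle],
                   variables: Sequence[str]) -> dict[str, float]:
    norms = {}
    for v in variables:
        mx = 0.0
        for ch in chronicles:
            col = getattr(ch, v)
            if col is not None and np.any(np.isfinite(col)):
                mx = max(mx, float(np.nanmax(np.abs(col))))
        if mx > 0:
            norms[v] = mx
    return norms


def _chronicle_init(ch: Chronicle) -> State:
    m = ch.meta
    if {"N0", "X0", "S0"} <= m.keys():
        return State(X=m["X0"], N=m["N0"], S=m["S0"],
                     E=m.get("E0", 0.0), CO2=m.get("CO2_0", 0.0))
    return ch.initial_state()


def fit_second_step(chronicles: Sequence[Chronicle],
                    gp: GrowthParams,
                    yf: YieldFunction,
                    init_guess: SecondStepParams,
                    fix_k: bool = True,
                    k: float = K_LITERATURE,
                    rtol: float = 1e-8,
                    atol: float = 1e-10,
                    fit_tol: float = 1e-10) -> FitResult:
    """Fit (beta, mu_S_max, K_S, K_E) on CO2 (and dCO2/dt) chronicles.

    Growth and yield parameters are held fixed; the stoichiometric yield k
    defaults to the literature value 2.17.  Residuals are computed on data
    normalized by the per-variable maximum over the whole dataset, so CO2
    and its rate carry comparable weight.  Each chronicle must expose its
    initial conditions (meta N0/X0/S0 or full first row).

    beta and mu_S_max enter the CO2 balance only through their product
    beta * mu_S_max, so they are not separately identifiable from
    chronicles: the optimization runs over the identifiable set
    (product, K_S, K_E) and the product is then split between beta and
    mu_S_max symmetrically in log space around the initial guess — the
    representative closest to the starting (literature) values.
    """
    chronicles = list(chronicles)
    if not chronicles:
        raise ValueError("need at least one chronicle")
    variables = ["CO2", "dCO2dt"]
    norms = _dataset_norms(chronicles, variables)
    if "CO2" not in norms and "dCO2dt" not in norms:
        raise ValueError("no CO2 signal in the chronicles (all zero or absent)")
    inits = [_chronicle_init(ch) for ch in chronicles]
    cfg_kw = dict(rtol=rtol, atol=atol)

    beta0, mus0 = init_guess.beta, init_guess.mu_S_max
    x0 = [beta0 * mus0, init_guess.K_S, init_guess.K_E]
    if not fix_k:
        x0.append(init_guess.k)

    def unpack(logp: np.ndarray) -> SecondStepParams:
        prod, K_S, K_E = np.exp(logp[:3])
        k_val = float(np.exp(logp[3])) if logp.size > 3 else k
        s = np.sqrt(prod / (beta0 * mus0))
        return SecondStepParams(k_val, beta0 * s, mus0 * s, K_S, K_E)

    def resid(logp: np.ndarray) -> np.ndarray:
        sp = unpack(logp)
        out = []
        for ch, init in zip(chronicles, inits):
            cfg = SimulationConfig(t_end=float(ch.time[-1]), **cfg_kw)
            sim = simulate(init, gp, yf, sp, cfg, times=ch.time)
            for v in variables:
                obs = getattr(ch, v)
                if obs is None or v not in norms:
                    continue
                m = np.isfinite(obs)
                out.append((getattr(sim, v)[m] - obs[m]) / norms[v])
        return np.concatenate(out)

    res = least_squares(resid, np.log(x0), method="lm", xtol=fit_tol,
                        ftol=fit_tol, max_nfev=2000)
    sp = unpack(res.x)
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    if not res.success:
        raise RuntimeError(
            f"second-step fit did not converge: {res.message}; best iterate "
            f"{sp}, normalized rmse={rmse:g}")
    return FitResult(params=sp, rmse=rmse, nfev=res.nfev,
                     message=res.message,
                     fixed={"k": fix_k, "growth": True, "yield": True})


def fit_all(chronicles: Sequence[Chronicle],
            endpoints: Optional[EndpointDataset],
            family: str = "quad_exp",
            N_dagger: Optional[float] = None,
            use_biomass: bool = False,
            init_growth: Optional[GrowthParams] = None,
            init_second: Optional[SecondStepParams] = None,
            k: float = K_LITERATURE,
            rtol: float = 1e-8,
            atol: float = 1e-10,
            fit_tol: float = 1e-10) -> FitResult:
    """Simultaneous fit of (mu_N_max, K_N, beta, mu_S_max, K_S, K_E).

    For chronicles without nitrogen measurements the growth kinetics cannot
    be identified separately, so all six parameters are fitted at once on
    the normalized CO2 trajectories (plus the biomass points when
    ``use_biomass``), with the yield function first calibrated on the
    endpoint dataset and then held fixed, and k at its literature value.
    The beta/mu_S_max product degeneracy is handled as in
    :func:`fit_second_step`.
    """
    if endpoints is None or len(endpoints) == 0:
        raise ValueError("endpoint dataset required: the yield function must "
                         "be calibrated before the simultaneous fit")
    yf_fit = _fit_yield_fixed(endpoints, family, N_dagger)
    yf = yf_fit.params

    chronicles = list(chronicles)
    if not chronicles:
        raise ValueError("need at least one chronicle")
    variables = ["CO2", "dCO2dt"] + (["X"] if use_biomass else [])
    norms = _dataset_norms(chronicles, variables)
    if "CO2" not in norms and "dCO2dt" not in norms:
        raise ValueError("no CO2 signal in the chronicles")
    inits = [_chronicle_init(ch) for ch in chronicles]

    g0 = init_growth or GrowthParams(0.2, 0.02)
    s0 = init_second or SecondStepParams(k, 2.0, 0.2, 20.0, 50.0)
    beta0, mus0 = s0.beta, s0.mu_S_max
    logx0 = np.log([g0.mu_N_max, g0.K_N, beta0 * mus0, s0.K_S, s0.K_E])

    def unpack(logp: np.ndarray) -> tuple[GrowthParams, SecondStepParams]:
        mu_n, K_N, prod, K_S, K_E = np.exp(logp)
        s = np.sqrt(prod / (beta0 * mus0))
        return (GrowthParams(mu_n, K_N),
                SecondStepParams(k, beta0 * s, mus0 * s, K_S, K_E))

    def resid(logp: np.ndarray) -> np.ndarray:
        gp, sp = unpack(logp)
        out = []
        for ch, init in zip(chronicles, inits):
            cfg = SimulationConfig(t_end=float(ch.time[-1]),
                                   rtol=rtol, atol=atol)
            sim = simulate(init, gp, yf, sp, cfg, times=ch.time)
            for v in variables:
                obs = getattr(ch, v)
                if obs is None or v not in norms:
                    continue
                m = np.isfinite(obs)
                out.append((getattr(sim, v)[m] - obs[m]) / norms[v])
        return np.concatenate(out)

    res = least_squares(resid, logx0, method="lm", xtol=fit_tol, ftol=fit_tol,
                        max_nfev=4000)
    gp, sp = unpack(res.x)
    if not res.success:
        raise RuntimeError(f"simultaneous fit did not converge: {res.message}; "
                           f"best iterate growth={gp}, second={sp}")
    # per-variable RMSE on the normalized scale
    per_var = {}
    for v in variables:
        out = []
        for ch, init in zip(chronicles, inits):
            obs = getattr(ch, v)
            if obs is None or v not in norms:
                continue
            cfg = SimulationConfig(t_end=float(ch.time[-1]), rtol=rtol, atol=atol)
            sim = simulate(init, gp, yf, sp, cfg, times=ch.time)
            m = np.isfinite(obs)
            out.append((getattr(sim, v)[m] - obs[m]) / norms[v])
        if out:
            per_var[v] = float(np.sqrt(np.mean(np.concatenate(out) ** 2)))
    return FitResult(params={"growth": gp, "yield": yf, "second_step": sp},
                     rmse=float(np.sqrt(np.mean(res.fun**2))),
                     nfev=res.nfev, message=res.message,
                     fixed={"k": True, "yield": True},
                     extra={"rmse_per_variable": per_var,
                            "yield_fit": yf_fit})


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def metrics(observed: Chronicle,
            simulated: Chronicle,
            variables: Optional[Sequence[str]] = None,
            normalize: bool = True) -> dict[str, float]:
    """Per-variable RMSE between an observed and a simulated chronicle.

    The simulated series is interpolated onto the observed times; with
    ``normalize`` each variable is divided by its maximum over the observed
    data first (so the result is scale-free, comparable across variables).
    """
    if variables is None:
        variables = [v for v in observed.columns if v in simulated.columns]
    out: dict[str, float] = {}
    for v in variables:
        obs = getattr(observed, v)
        sim = getattr(simulated, v)
        if obs is None or sim is None:
            raise ValueError(f"variable {v} missing from one chronicle")
        lo = max(observed.time[0], simulated.time[0])
        hi = min(observed.time[-1], simulated.time[-1])
        m = (observed.time >= lo) & (observed.time <= hi) & np.isfinite(obs)
        if not m.any():
            raise ValueError(f"no overlapping time points for variable {v}")
        sim_i = np.interp(observed.time[m], simulated.time, sim)
        diff = sim_i - obs[m]
        if normalize:
            scale = float(np.nanmax(np.abs(obs[m])))
            if scale == 0:
                raise ValueError(f"cannot normalize {v}: observed max is 0")
            diff = diff / scale
        out[v] = float(np.sqrt(np.mean(diff**2)))
    return out
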