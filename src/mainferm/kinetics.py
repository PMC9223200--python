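"""Rate laws and yield/maintenance functions for nitrogen-limited wine fermentation.

The growth step models yeast growing on assimilable nitrogen ``N`` with a
ratio-dependent (Contois) kinetics, while part of the consumed nitrogen is
diverted to maintenance rather than converted into biomass.  Maintenance is
taken proportional to the growth activity,

    m(N, X) = alpha(N) * mu_N(N, X),        alpha(0) = 0,  alpha >= 0,

which is algebraically equivalent to replacing the constant growth yield ``Y``
by a nitrogen-dependent *variable yield*

    y(N) = Y / (1 + alpha(N) * Y),          Y = y(0).

The variable yield is what is actually identifiable from batch data: for an
exhausted fermentation the total biomass produced satisfies

    X(inf) - X(0) = integral_0^{N(0)} y(n) dn = f(N(0)),       f(0) = 0,

so fitting the endpoint curve ``f`` and differentiating gives ``y = f'``,
and from it ``alpha`` and the maintenance function.  Two closed-form families
for ``f`` are provided (a linear family with a cubic smoothing branch below a
threshold ``N_dagger``, and a quadratic family continued exponentially above
``N_dagger``) together with the degenerate constant-yield family.

The sugar-to-ethanol step uses Monod kinetics in sugar with hyperbolic
ethanol inhibition; see :mod:`mainferm.simulator` for the coupled ODE system.

Units throughout: concentrations in g/L, time in hours, rates in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

__all__ = [
    "State",
    "GrowthParams",
    "SecondStepParams",
    "YieldFunction",
    "YieldLinearSmoothed",
    "YieldQuadExp",
    "YieldConstant",
    "FunctionalYield",
    "contois_rate",
    "monod_rate",
    "ethanol_inhibition",
    "yield_f",
    "yield_y",
    "alpha",
    "maintenance_m",
    "yield_from_maintenance",
]


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


def _check_pos(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class State:
    """Fermentation state: concentrations at one instant (g/L).

    Attributes
    ----------
    X : biomass
    N : total assimilable nitrogen
    S : sugar
    E : ethanol
    CO2 : carbon dioxide produced
    """

    X: float
    N: float
    S: float
    E: float = 0.0
    CO2: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg(X=self.X, N=self.N, S=self.S, E=self.E, CO2=self.CO2)

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.N, self.S, self.E, self.CO2], float)

    @classmethod
    def from_array(cls, v: np.ndarray) -> "State":
        return cls(*(max(float(x), 0.0) for x in v))


@dataclass(frozen=True)
class GrowthParams:
    """Contois growth parameters: mu = mu_N_max * N / (N + K_N * X)."""

    mu_N_max: float  # maximal specific growth rate (1/h)
    K_N: float       # Contois affinity constant (g/L per g/L of biomass)

    def __post_init__(self) -> None:
        _check_pos(mu_N_max=self.mu_N_max, K_N=self.K_N)


@dataclass(frozen=True)
class SecondStepParams:
    """Parameters of the sugar -> ethanol + CO2 conversion.

    ``k`` is the stoichiometric sugar-per-CO2 yield (g/g), ``beta`` the
    coupling factor of the sugar pathway, ``mu_S_max``/``K_S`` the Monod
    constants in sugar, and ``K_E`` the ethanol inhibition constant (g/L):
    the pathway rate is (mu_N + beta * mu_S(S) / (1 + E/K_E)) * X.
    """

    k: float
    beta: float
    mu_S_max: float
    K_S: float
    K_E: float

    def __post_init__(self) -> None:
        _check_pos(k=self.k, beta=self.beta, mu_S_max=self.mu_S_max,
                   K_S=self.K_S, K_E=self.K_E)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def contois_rate(N: float, X: float, p: GrowthParams) -> float:
    """Specific growth rate mu_N_max * N / (N + K_N * X), in 1/h.

    Ratio-dependent in r = N/X, so growth slows under biomass excess.
    The 0/0 corner N = X = 0 is defined as 0 (no substrate, no growth).
    """
    if N < 0 or X < 0:
        raise ValueError("N and X must be non-negative")
    if N == 0.0:
        return 0.0
    return p.mu_N_max * N / (N + p.K_N * X)


def monod_rate(S: float, p: SecondStepParams) -> float:
    """Monod specific rate mu_S_max * S / (K_S + S), in 1/h."""
    if S < 0:
        raise ValueError("S must be non-negative")
    return p.mu_S_max * S / (p.K_S + S)


def ethanol_inhibition(E: float, p: SecondStepParams) -> float:
    """Hyperbolic inhibition factor 1 / (1 + E/K_E), in (0, 1]."""
    if E < 0:
        raise ValueError("E must be non-negative")
    return 1.0 / (1.0 + E / p.K_E)


# ---------------------------------------------------------------------------
# yield families
# ---------------------------------------------------------------------------

class YieldFunction:
    """Abstract variable-yield family.

    Concrete families provide ``f`` (cumulative biomass potential, f(0)=0,
    increasing) and ``y = f'`` (instantaneous biomass-per-nitrogen yield,
    positive).  ``alpha(N) = 1/y(N) - 1/y(0)`` is derived and describes the
    maintenance intensity relative to growth.
    """

    family: str = "abstract"

    def f(self, N):
        raise NotImplementedError

    def y(self, N):
        raise NotImplementedError

    def alpha(self, N):
        """Maintenance factor 1/y(N) - 1/y(0); zero at N=0, non-negative."""
        yN = np.asarray(self.y(N), float)
        out = 1.0 / yN - 1.0 / float(self.y(0.0))
        return out if out.ndim else float(out)

    def params_dict(self) -> dict:
        raise NotImplementedError

    def y_scalar(self, n: float) -> float:
        """Scalar fast path for y(N), used in ODE right-hand sides."""
        return float(self.y(n))


@dataclass(frozen=True)
class YieldLinearSmoothed(YieldFunction):
    """Linear endpoint curve with a cubic smoothing branch below ``N_dagger``.

    f(N) = a*N + b*(1 - ((Nd - N)/Nd)^3)   for N <  Nd
         = a*N + b                          for N >= Nd

    so y = f' equals ``a`` above the threshold and rises smoothly to
    a + 3b/Nd at N = 0.  C2 in f / C1 in y at the junction by construction.
    The asymptotic slope ``a`` is the high-nitrogen yield (g biomass per g N)
    and the intercept ``b`` (g/L) is the endpoint-line offset whose
    non-nullity is the signature of maintenance.
    """

    a: float
    b: float
    N_dagger: float
    family: str = field(default="linear_smoothed", init=False, repr=False)

    def __post_init__(self) -> None:
        _check_pos(a=self.a, b=self.b, N_dagger=self.N_dagger)

    def f(self, N):
        N = np.asarray(N, float)
        if np.any(N < 0):
            raise ValueError("N must be non-negative")
        Nd = self.N_dagger
        low = self.a * N + self.b * (1.0 - ((Nd - N) / Nd) ** 3)
        high = self.a * N + self.b
        out = np.where(N < Nd, low, high)
        return out if out.ndim else float(out)

    def y(self, N):
        N = np.asarray(N, float)
        if np.any(N < 0):
            raise ValueError("N must be non-negative")
        Nd = self.N_dagger
        low = self.a + 3.0 * self.b * (Nd - N) ** 2 / Nd**3
        out = np.where(N < Nd, low, self.a)
        return out if out.ndim else float(out)

    def y_scalar(self, n: float) -> float:
        Nd = self.N_dagger
        if n >= Nd:
            return self.a
        return self.a + 3.0 * self.b * (Nd - n) ** 2 / Nd**3

    def params_dict(self) -> dict:
        return {"family": self.family, "a": self.a, "b": self.b,
                "N_dagger": self.N_dagger}


@dataclass(frozen=True)
class YieldQuadExp(YieldFunction):
    """Quadratic endpoint curve continued exponentially above ``N_dagger``.

    y(N) = b - 2aN            for N <  Nd
         = A * exp(-B*N)      for N >= Nd

    with A = (b - 2a*Nd) * exp(B*Nd) and B = 2a / (b - 2a*Nd), the unique
    C1 continuation of the quadratic branch (y and y' continuous at Nd).
    f is the C2 antiderivative with f(0) = 0:

    f(N) = bN - aN^2                                        for N <  Nd
         = f(Nd) + (A/B) * (exp(-B*Nd) - exp(-B*N))         for N >= Nd

    Requires b - 2a*Nd > 0 so that the yield stays positive.  ``b`` is the
    yield at N = 0 (g/g) and ``a`` the curvature of the endpoint curve.
    """

    a: float
    b: float
    N_dagger: float
    family: str = field(default="quad_exp", init=False, repr=False)

    def __post_init__(self) -> None:
        _check_pos(b=self.b, N_dagger=self.N_dagger)
        if self.b - 2.0 * self.a * self.N_dagger <= 0:
            raise ValueError(
                "invalid quad_exp family: b - 2*a*N_dagger must be > 0 "
                f"(got {self.b - 2.0 * self.a * self.N_dagger:g})")

    @property
    def B(self) -> float:
        return 2.0 * self.a / (self.b - 2.0 * self.a * self.N_dagger)

    @property
    def A(self) -> float:
        return (self.b - 2.0 * self.a * self.N_dagger) * np.exp(self.B * self.N_dagger)

    def f(self, N):
        N = np.asarray(N, float)
        if np.any(N < 0):
            raise ValueError("N must be non-negative")
        a, b, Nd = self.a, self.b, self.N_dagger
        A, B = self.A, self.B
        f_nd = b * Nd - a * Nd**2
        low = b * N - a * N**2
        high = f_nd + (A / B) * (np.exp(-B * Nd) - np.exp(-B * np.minimum(N, 1e30)))
        out = np.where(N < Nd, low, high)
        return out if out.ndim else float(out)

    def y(self, N):
        N = np.asarray(N, float)
        if np.any(N < 0):
            raise ValueError("N must be non-negative")
        low = self.b - 2.0 * self.a * N
        high = self.A * np.exp(-self.B * N)
        out = np.where(N < self.N_dagger, low, high)
        return out if out.ndim else float(out)

    def y_scalar(self, n: float) -> float:
        if n < self.N_dagger:
            return self.b - 2.0 * self.a * n
        return self.A * float(np.exp(-self.B * n))

    def params_dict(self) -> dict:
        return {"family": self.family, "a": self.a, "b": self.b,
                "N_dagger": self.N_dagger}


@dataclass(frozen=True)
class YieldConstant(YieldFunction):
    """Constant yield Y: the maintenance-free limit (alpha = 0, f = Y*N)."""

    Y: float
    family: str = field(default="constant", init=False, repr=False)

    def __post_init__(self) -> None:
        _check_pos(Y=self.Y)

    def f(self, N):
        N = np.asarray(N, float)
        if np.any(N < 0):
            raise ValueError("N must be non-negative")
        out = self.Y * N
        return out if out.ndim else float(out)

    def y(self, N):
        N = np.asarray(N, float)
        out = np.full_like(N, self.Y)
        return out if out.ndim else float(out)

    def y_scalar(self, n: float) -> float:
        return self.Y

    def params_dict(self) -> dict:
        return {"family": self.family, "Y": self.Y}


class FunctionalYield(YieldFunction):
    """Yield function assembled from a zero-nitrogen yield and a maintenance
    factor alpha(N), via y(N) = Y / (1 + alpha(N) * Y).

    ``f`` is obtained by numerical quadrature of ``y``; use a closed-form
    family when one is available.
    """

    family = "functional"

    def __init__(self, Y: float, alpha_fn: Callable[[float], float]):
        _check_pos(Y=Y)
        a0 = float(alpha_fn(0.0))
        if abs(a0) > 1e-12:
            raise ValueError(f"alpha(0) must be 0 (got {a0:g})")
        self.Y = float(Y)
        self._alpha_fn = alpha_fn

    def y(self, N):
        N = np.asarray(N, float)
        a = np.vectorize(self._alpha_fn, otypes=[float])(N)
        out = self.Y / (1.0 + a * self.Y)
        return out if out.ndim else float(out)

    def f(self, N):
        scalar = np.isscalar(N) or np.ndim(N) == 0
        Ns = np.atleast_1d(np.asarray(N, float))
        if np.any(Ns < 0):
            raise ValueError("N must be non-negative")
        vals = np.array([quad(lambda n: self.y(n), 0.0, x, limit=200)[0]
                         for x in Ns])
        return float(vals[0]) if scalar else vals

    def alpha(self, N):
        N = np.asarray(N, float)
        out = np.vectorize(self._alpha_fn, otypes=[float])(N)
        return out if out.ndim else float(out)

    def params_dict(self) -> dict:
        return {"family": self.family, "Y": self.Y}


# ---------------------------------------------------------------------------
# functional wrappers (module-level operations)
# ---------------------------------------------------------------------------

def yield_f(N, yf: YieldFunction):
    """Cumulative biomass potential f(N) = integral_0^N y(n) dn (g/L)."""
    return yf.f(N)


def yield_y(N, yf: YieldFunction):
    """Instantaneous biomass-per-nitrogen yield y(N) = f'(N) (g/g)."""
    return yf.y(N)


def alpha(N, yf: YieldFunction):
    """Maintenance factor alpha(N) = 1/y(N) - 1/y(0)."""
    return yf.alpha(N)


def maintenance_m(N: float, X: float, gp: GrowthParams, yf: YieldFunction) -> float:
    """Maintenance rate m(N, X) = alpha(N) * mu_N(N, X), in g N / (g X h).

    Vanishes at N = 0: maintenance stops with the growth activity, so the
    nitrogen balance cannot push N negative after exhaustion.
    """
    return float(yf.alpha(N)) * contois_rate(N, X, gp)


def yield_from_maintenance(Y: float, alpha_fn: Callable[[float], float]) -> FunctionalYield:
    """Build the variable yield y(N) = Y / (1 + alpha(N) Y) from a maintenance
    factor; exact algebraic inverse of :func:`alpha`."""
    return FunctionalYield(Y, alpha_fn)
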