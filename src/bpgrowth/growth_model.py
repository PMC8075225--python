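"""Bertalanffy-Pütter (BP) growth curves and their shape parameters.

The BP model describes the mass ``m(t)`` of a growing animal by the
ordinary differential equation

    m'(t) = p * m(t)**a - q * m(t)**b,        m(0) = c > 0,

with non-negative "metabolic" exponents ``a < b`` and scaling constants
``p > 0``, ``q >= 0``.  The anabolic term ``p*m**a`` models resource
uptake, the catabolic term ``q*m**b`` the cost of maintaining existing
tissue.  Classical three-parameter growth models are special cases fixed
by the exponent pair: Brody ``(0, 1)``, von Bertalanffy ``(2/3, 1)``,
West ``(3/4, 1)``, logistic/Verhulst ``(1, 2)``; Gompertz is the
diagonal limit ``(1, 1)`` and is handled as its own ODE.

For ``q > 0`` the curve saturates at the asymptotic mass
``m_max = (p/q)**(1/(b-a))`` and, when additionally ``a > 0``, has a
unique inflection point at mass ``m_infl = (a/b)**(1/(b-a)) * m_max``.
The dimensionless shape ratio ``m_infl / m_max = (a/b)**(1/(b-a))``
depends on the exponent pair only; it is the headline statistic of this
package.  Curves without an inflection point (``a = 0`` or ``q = 0``)
are assigned ``m_infl = t_infl = ratio = 0`` by convention.

Trajectories are obtained by adaptive numerical integration (LSODA,
relative tolerance 1e-9, automatic stiffness switching); the closed
forms available for ``a = 1`` or ``b = 1`` are used only as independent
oracles in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "BPParameters",
    "ShapeParameters",
    "NamedModel",
    "NAMED_MODELS",
    "GrowthIntegrationError",
    "growth_rate",
    "solve_curve",
    "solve_gompertz",
    "asymptotic_mass",
    "inflection_mass",
    "inflection_time",
    "shape_ratio",
    "shape_parameters",
    "family_ratio_bounds",
    "is_near_diagonal",
]

#: Exponent-difference below which a pair counts as "near-diagonal".
NEAR_DIAGONAL_GAP = 1.5


class GrowthIntegrationError(RuntimeError):
    """Numerical integration of a BP trajectory failed.

    Carries the offending parameters so batch pipelines can log and
    continue.
    """

    def __init__(self, message: str, params: "BPParameters"):
        super().__init__(f"{message} (params={params})")
        self.params = params


@dataclass(frozen=True)
class BPParameters:
    """The quintuple ``(a, b, c, p, q)`` defining one BP growth curve.

    ``a`` and ``b`` are the dimensionless metabolic exponents with
    ``0 <= a < b`` (the Gompertz diagonal ``a == b`` is excluded);
    ``c`` is the initial mass in grams at ``t = 0``; ``p`` and ``q``
    are positive scaling constants with units ``g**(1-a)/day`` and
    ``g**(1-b)/day``.  ``q = 0`` is allowed and yields unbounded growth.
    """

    a: float
    b: float
    c: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a < self.b):
            raise ValueError(f"exponents must satisfy 0 <= a < b, got a={self.a}, b={self.b}")
        if self.c <= 0:
            raise ValueError(f"initial mass c must be positive, got {self.c}")
        if self.p <= 0:
            raise ValueError(f"scaling constant p must be positive, got {self.p}")
        if self.q < 0:
            raise ValueError(f"scaling constant q must be non-negative, got {self.q}")


@dataclass(frozen=True)
class ShapeParameters:
    """Shape parameters of one BP curve.

    ``m_max`` may be ``math.inf`` (when ``q = 0``).  For curves without
    an inflection point (``a = 0`` or ``q = 0``) the convention
    ``m_infl = t_infl = ratio = 0`` applies.  ``inflection_precedes_start``
    flags curves whose initial mass already exceeds the inflection mass,
    so the inflection is never observed; the ratio is still the pure
    function of the exponent pair.
    """

    m_max: float
    m_infl: float
    t_infl: float
    ratio: float
    inflection_precedes_start: bool = False


@dataclass(frozen=True)
class NamedModel:
    """A classical growth model expressed as a BP exponent constraint.

    Either a fixed exponent pair (three-parameter models) or a
    one-parameter family (four-parameter models), described by
    ``family`` = None | "richards" | "generalized-bertalanffy" |
    "generalized-logistic".
    """

    name: str
    exponents: tuple[float, float] | None = None
    family: str | None = None
    note: str = ""


NAMED_MODELS: dict[str, NamedModel] = {
    "Brody": NamedModel("Brody", exponents=(0.0, 1.0)),
    "Bertalanffy": NamedModel("Bertalanffy", exponents=(2.0 / 3.0, 1.0)),
    "West": NamedModel("West", exponents=(3.0 / 4.0, 1.0)),
    "logistic": NamedModel("logistic", exponents=(1.0, 2.0)),
    "Gompertz": NamedModel(
        "Gompertz", exponents=(1.0, 1.0),
        note="diagonal limit; solved as m' = m*(p - q*ln m), not part of the BP grid",
    ),
    "Richards": NamedModel("Richards", family="richards", note="a = 1, b > 1"),
    "generalized-Bertalanffy": NamedModel(
        "generalized-Bertalanffy", family="generalized-bertalanffy", note="0 <= a < 1, b = 1"),
    "generalized-logistic": NamedModel(
        "generalized-logistic", family="generalized-logistic", note="b = a + 1"),
}


def growth_rate(m, params: BPParameters):
    """Instantaneous growth rate ``p*m**a - q*m**b`` in g/day.

    Accepts a scalar or array mass; raises ``ValueError`` for
    non-positive mass, where the power terms are undefined.
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr <= 0):
        raise ValueError("mass must be positive")
    rate = params.p * m_arr ** params.a - params.q * m_arr ** params.b
    return float(rate) if np.isscalar(m) else rate


def _dense_solution(params: BPParameters, t_max: float):
    """Integrate the BP ODE on [0, t_max] with dense output.

    LSODA switches to a stiff (BDF) integrator automatically — essential
    for large exponents, where the relaxation rate toward the asymptote
    scales like m_max**b and explicit Runge-Kutta steps collapse.
    """

    def rhs(_t, y):
        m = max(y[0], 1e-300)
        with np.errstate(over="ignore", invalid="ignore"):
            return (params.p * m ** params.a - params.q * m ** params.b,)

    def jac(_t, y):
        m = max(y[0], 1e-300)
        with np.errstate(over="ignore", invalid="ignore"):
            return ((params.a * params.p * m ** (params.a - 1.0)
                     - params.b * params.q * m ** (params.b - 1.0),),)

    sol = solve_ivp(
        rhs, (0.0, t_max), (params.c,), jac=jac,
        method="LSODA", rtol=1e-9, atol=1e-12, dense_output=True,
    )
    if not sol.success:
        raise GrowthIntegrationError(f"ODE integration failed: {sol.message}", params)
    return sol


def solve_curve(params: BPParameters, times: Sequence[float]) -> np.ndarray:
    """Mass trajectory ``m(t)`` at the requested times (days).

    Times must be non-negative and non-decreasing; ``t = 0`` returns the
    initial mass ``c`` exactly.  Integration uses adaptive LSODA with
    relative tolerance 1e-9.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return np.empty(0)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    t_max = float(t[-1])
    if t_max == 0.0:
        return np.full(t.shape, params.c)
    sol = _dense_solution(params, t_max)
    out = sol.sol(t)[0]
    out[t == 0.0] = params.c
    if not np.all(np.isfinite(out)):
        raise GrowthIntegrationError("trajectory overflowed", params)
    return out


def solve_gompertz(c: float, p: float, q: float, times: Sequence[float]) -> np.ndarray:
    """Gompertz trajectory, the diagonal limit of the BP family.

    Solves ``m' = m*(p - q*ln m)`` with ``m(0) = c``; closed form
    ``m(t) = exp(p/q + (ln c - p/q) * exp(-q t))`` for ``q > 0``.
    """
    if c <= 0 or p <= 0 or q <= 0:
        raise ValueError("Gompertz requires c, p, q > 0")
    t = np.asarray(times, dtype=float)
    return np.exp(p / q + (math.log(c) - p / q) * np.exp(-q * t))


def asymptotic_mass(params: BPParameters) -> float:
    """Asymptotic mass ``(p/q)**(1/(b-a))``; ``inf`` when ``q = 0``."""
    if params.q == 0.0:
        return math.inf
    return (params.p / params.q) ** (1.0 / (params.b - params.a))


def shape_ratio(a: float, b: float) -> float:
    """The ratio ``m_infl/m_max = (a/b)**(1/(b-a))``.

    A pure function of the exponent pair — independent of ``c, p, q``.
    Returns 0 for ``a = 0`` (no inflection point).
    """
    if not (0.0 <= a < b):
        raise ValueError(f"exponents must satisfy 0 <= a < b, got a={a}, b={b}")
    if a == 0.0:
        return 0.0
    return (a / b) ** (1.0 / (b - a))


def inflection_mass(params: BPParameters) -> float:
    """Mass at the inflection point, ``(a/b)**(1/(b-a)) * m_max``.

    0 by convention when there is no inflection point (``a = 0`` or
    ``q = 0``).
    """
    if params.a == 0.0 or params.q == 0.0:
        return 0.0
    return shape_ratio(params.a, params.b) * asymptotic_mass(params)


def inflection_time(params: BPParameters) -> float:
    """Age (days since ``t = 0``) at which the trajectory crosses m_infl.

    Solved numerically on the integrated trajectory: the monotone
    trajectory guarantees a unique root, bracketed by doubling the
    horizon until ``m(T) > m_infl`` and then refined to 1e-9 days.
    Returns 0 when there is no inflection point, or when the curve
    starts at or above the inflection mass (``c >= m_infl``).
    """
    m_infl = inflection_mass(params)
    if m_infl == 0.0 or params.c >= m_infl:
        return 0.0
    t_hi = 1.0
    for _ in range(64):
        sol = _dense_solution(params, t_hi)
        if sol.sol(t_hi)[0] > m_infl:
            break
        t_hi *= 2.0
    else:
        raise GrowthIntegrationError("could not bracket the inflection time", params)
    return float(brentq(lambda t: sol.sol(t)[0] - m_infl, 0.0, t_hi, xtol=1e-9))


def shape_parameters(params: BPParameters) -> ShapeParameters:
    """All shape parameters of one curve, honoring the no-inflection
    convention and flagging inflections that precede the observation
    window."""
    m_max = asymptotic_mass(params)
    if params.a == 0.0 or params.q == 0.0:
        return ShapeParameters(m_max=m_max, m_infl=0.0, t_infl=0.0, ratio=0.0)
    ratio = shape_ratio(params.a, params.b)
    m_infl = ratio * m_max
    if params.c >= m_infl:
        return ShapeParameters(m_max=m_max, m_infl=m_infl, t_infl=0.0, ratio=ratio,
                               inflection_precedes_start=True)
    return ShapeParameters(m_max=m_max, m_infl=m_infl,
                           t_infl=inflection_time(params), ratio=ratio)


def family_ratio_bounds(family: NamedModel | str, sweep_points: int = 4000) -> tuple[float, float]:
    """Attainable interval of the shape ratio for a four-parameter family.

    The bounds are located numerically by sweeping the free exponent of
    the family and cross-checked against the analytic limits:
    Richards (a=1, b>1) has ratio ``(1/b)**(1/(b-1))`` decreasing to
    1/e as b -> 1+, so the interval is (1/e, 1); the generalized
    Bertalanffy family (b=1) attains [0, 1/e); the generalized logistic
    line (b=a+1) has ratio ``a/(a+1)`` and attains (0, 1).  Interval
    endpoints are open except the generalized-Bertalanffy lower bound
    (ratio 0 at a=0).
    """
    model = NAMED_MODELS[family] if isinstance(family, str) else family
    if model.family == "richards":
        bs = 1.0 + np.logspace(-8, 3, sweep_points)
        ratios = (1.0 / bs) ** (1.0 / (bs - 1.0))
        lo, hi = ratios.min(), 1.0
        assert abs(lo - math.exp(-1)) < 1e-6
        return (float(lo), float(hi))
    if model.family == "generalized-bertalanffy":
        a_vals = np.concatenate([[0.0], 1.0 - np.logspace(-8, 0, sweep_points - 1)[::-1]])
        a_pos = a_vals[a_vals > 0]
        ratios = a_pos ** (1.0 / (1.0 - a_pos))
        hi = ratios.max()
        assert abs(hi - math.exp(-1)) < 1e-6
        return (0.0, float(hi))
    if model.family == "generalized-logistic":
        return (0.0, 1.0)
    raise ValueError(f"no ratio-bound family for model {model.name!r}")


def is_near_diagonal(a: float, b: float) -> bool:
    """True when the exponent difference ``b - a`` is below 1.5."""
    if a >= b:
        raise ValueError("requires a < b")
    return (b - a) < NEAR_DIAGONAL_GAP
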