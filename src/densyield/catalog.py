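"""Catalog of candidate density-response curve families.

Maize planting-density trials produce two characteristic response shapes:
population (per-area) relative yield rises to a single interior optimum and
then falls under crowding stress, while relative single-plant yield declines
monotonically toward a small asymptote.  Historically these responses were
screened against a library of two- to four-parameter curve families and the
best-fitting, biologically plausible family was retained — the Hoerl family
``y = a·bˣ·xᶜ`` for population yield and the Weibull-type decline
``y = m − n·e^(−p·xᵗ)`` for single-plant yield.

This module holds that candidate library: each :class:`CurveModel` bundles a
vectorised evaluator, an analytic derivative where the family has a tractable
closed form (central finite differences otherwise), symbolic limit rules for
x→0⁺ and x→∞ used by the plausibility screen, admissible parameter intervals,
and data-driven starting values for nonlinear least squares.

Families are registered once even when they serve both response roles; the
``roles`` tag records whether a family belongs to the population ranking, the
single-plant ranking, or both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import (
    CatalogError,
    DensityDomainError,
    ParameterDomainError,
    UnsupportedFamilyError,
)

__all__ = [
    "CurveModel",
    "HoerlParams",
    "WeibullParams",
    "CATALOG",
    "POPULATION_FAMILIES",
    "SINGLE_PLANT_FAMILIES",
    "get_model",
    "evaluate",
    "derivative",
    "limit_behavior",
    "numeric_limit_probe",
    "export_catalog",
]

_EXP_CAP = 709.0  # log of the largest double; exponents above this -> inf

INF = math.inf


def _safe_exp(z: np.ndarray | float) -> np.ndarray:
    """exp() that overflows to inf and underflows to 0 without warnings."""
    z = np.asarray(z, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        out = np.exp(np.minimum(z, _EXP_CAP + 1.0))
    return out


def _sign_inf(coef: float) -> float:
    return INF if coef > 0 else -INF


@dataclass(frozen=True)
class HoerlParams:
    """Hoerl population-response parameters ``y = a·bˣ·xᶜ``.

    ``a`` scales the yield range before the optimum is reached, ``b`` in
    (0, 1) is the post-optimum decline base, ``c`` > 0 the pre-optimum rise
    exponent.  ``b`` and ``c`` jointly fix the optimal density −c/ln b.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ParameterDomainError(f"Hoerl a must be > 0, got {self.a}")
        if not (0 < self.b < 1):
            raise ParameterDomainError(f"Hoerl b must be in (0, 1), got {self.b}")
        if not (self.c > 0):
            raise ParameterDomainError(f"Hoerl c must be > 0, got {self.c}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


@dataclass(frozen=True)
class WeibullParams:
    """Weibull-type single-plant decline parameters ``y = m − n·e^(−p·xᵗ)``.

    With rate ``p`` > 0 and shape ``t`` < 0 the curve falls from the
    low-density plateau ``m`` toward the high-density asymptote ``m − n``.
    """

    m: float
    n: float
    p: float
    t: float

    def __post_init__(self) -> None:
        if not (self.p > 0):
            raise ParameterDomainError(f"Weibull p must be > 0, got {self.p}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.m, self.n, self.p, self.t)


@dataclass(frozen=True)
class CurveModel:
    """One candidate curve family.

    ``bounds`` are the admissible (open) parameter intervals enforced as hard
    checks at evaluation time and as box bounds during fitting.  ``limits``
    returns the symbolic pair (lim x→0⁺, lim x→∞); ``math.nan`` encodes
    "no limit exists" (oscillatory families).
    """

    id: str
    formula_text: str
    param_names: tuple[str, ...]
    value: Callable[[np.ndarray, np.ndarray], np.ndarray]
    roles: frozenset[str]
    bounds: tuple[tuple[float, float], ...]
    limits: Callable[[Sequence[float]], tuple[float, float]] | None = None
    deriv: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    start_candidates: Callable[[np.ndarray, np.ndarray], list[np.ndarray]] | None = None
    notes: str = ""

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def has_closed_derivative(self) -> bool:
        return self.deriv is not None

    def check_params(self, params: Sequence[float]) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ParameterDomainError(
                f"{self.id} expects {self.n_params} parameters "
                f"({', '.join(self.param_names)}), got {params.size}"
            )
        if not np.all(np.isfinite(params)):
            raise ParameterDomainError(f"{self.id}: parameters must be finite")
        for name, val, (lo, hi) in zip(self.param_names, params, self.bounds):
            if not (lo < val < hi):
                raise ParameterDomainError(
                    f"{self.id}: parameter {name}={val} outside admissible "
                    f"interval ({lo}, {hi})"
                )
        return params


CATALOG: dict[str, CurveModel] = {}


def _register(model: CurveModel) -> CurveModel:
    if model.id in CATALOG:
        raise ValueError(f"duplicate family id {model.id}")
    CATALOG[model.id] = model
    return model


FREE = (-INF, INF)
POS = (0.0, INF)


# ---------------------------------------------------------------------------
# value / derivative / limit / start rules, one block per family
# ---------------------------------------------------------------------------

def _v_cubic(p, x):
    a, b, c, d = p
    return a + x * (b + x * (c + x * d))


def _d_cubic(p, x):
    _, b, c, d = p
    return b + 2 * c * x + 3 * d * x * x


def _lim_cubic(p):
    a, b, c, d = p
    for coef in (d, c, b):
        if coef != 0:
            return (a, _sign_inf(coef))
    return (a, a)


def _s_cubic(x, y):
    return [np.polyfit(x, y, 3)[::-1]]


def _v_rational(p, x):
    a, b, c, d = p
    return (a + b * x) / (1.0 + x * (c + d * x))


def _lim_rational(p):
    a, b, c, d = p
    if d != 0:
        hi = 0.0
    elif c != 0:
        hi = b / c
    elif b != 0:
        hi = _sign_inf(b)
    else:
        hi = a
    return (a, hi)


def _s_rational(x, y):
    # linearise: y + c*x*y + d*x^2*y = a + b*x
    A = np.column_stack([np.ones_like(x), x, -x * y, -x * x * y])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return [coef]


def _v_hoerl(p, x):
    a, b, c = p
    # log-space form keeps x = 1e8 probes finite (underflow -> 0)
    return _safe_exp(math.log(a) + x * math.log(b) + c * np.log(x))


def _d_hoerl(p, x):
    a, b, c = p
    lnb = math.log(b)
    core = _safe_exp(math.log(a) + x * lnb + (c - 1.0) * np.log(x))
    return core * (x * lnb + c)


def _lim_hoerl(p):
    a, b, c = p
    lo = 0.0 if c > 0 else (a if c == 0 else INF)
    if b < 1:
        hi = 0.0
    elif b == 1:
        hi = INF if c > 0 else (a if c == 0 else 0.0)
    else:
        hi = INF
    return (lo, hi)


def _s_hoerl(x, y):
    # ln y = ln a + x ln b + c ln x  (linear in the logs)
    mask = y > 0
    if mask.sum() >= 3:
        A = np.column_stack([np.ones(mask.sum()), x[mask], np.log(x[mask])])
        coef, *_ = np.linalg.lstsq(A, np.log(y[mask]), rcond=None)
        la, lnb, c = coef
        cand = np.array([math.exp(la), math.exp(min(lnb, -1e-6)), max(c, 1e-3)])
        return [cand, np.array([0.5, 0.91, 0.8])]
    return [np.array([0.5, 0.91, 0.8])]


def _v_hoerl_mod(p, x):
    a, b, c = p
    return a * _safe_exp(math.log(b) / x + c * np.log(x))


def _lim_hoerl_mod(p):
    a, b, c = p
    if b < 1:
        lo = 0.0
    elif b == 1:
        lo = 0.0 if c > 0 else (a if c == 0 else INF)
    else:
        lo = _sign_inf(a)
    if c < 0:
        hi = 0.0
    elif c == 0:
        hi = a
    else:
        hi = _sign_inf(a)
    return (lo, hi)


def _s_hoerl_mod(x, y):
    mask = y > 0
    if mask.sum() >= 3:
        A = np.column_stack([np.ones(mask.sum()), 1.0 / x[mask], np.log(x[mask])])
        coef, *_ = np.linalg.lstsq(A, np.log(y[mask]), rcond=None)
        la, lnb, c = coef
        return [np.array([math.exp(la), math.exp(lnb), c])]
    return [np.array([1.0, 0.5, -0.5])]


def _v_exp_log(p, x):
    a, b, c = p
    return _safe_exp(a + b / x + c * np.log(x))


def _lim_exp_log(p):
    a, b, c = p
    if b < 0:
        lo = 0.0
    elif b > 0:
        lo = INF
    else:
        lo = 0.0 if c > 0 else (math.exp(a) if c == 0 else INF)
    if c < 0:
        hi = 0.0
    elif c == 0:
        hi = math.exp(a)
    else:
        hi = INF
    return (lo, hi)


def _s_exp_log(x, y):
    mask = y > 0
    if mask.sum() >= 3:
        A = np.column_stack([np.ones(mask.sum()), 1.0 / x[mask], np.log(x[mask])])
        coef, *_ = np.linalg.lstsq(A, np.log(y[mask]), rcond=None)
        return [coef]
    return [np.array([0.0, -1.0, -0.5])]


def _v_weibull(p, x):
    m, n, pp, t = p
    return m - n * _safe_exp(-pp * np.power(x, t))


def _d_weibull(p, x):
    m, n, pp, t = p
    return n * pp * t * np.power(x, t - 1.0) * _safe_exp(-pp * np.power(x, t))


def _lim_weibull(p):
    m, n, pp, t = p
    if t < 0:
        return (m, m - n)
    if t > 0:
        return (m - n, m)
    const = m - n * math.exp(-pp)
    return (const, const)


def _s_weibull(x, y):
    ymax, ymin = float(np.max(y)), float(np.min(y))
    span = max(ymax - ymin, 1e-3)
    out = []
    for t0 in (-2.5, -1.5, -0.8, 0.8, 1.5, 2.5):
        for p0 in (0.1, 1.0, 5.0, 20.0):
            if t0 < 0:
                out.append(np.array([ymax, span, p0, t0]))
            else:
                out.append(np.array([ymax, ymax - ymin, p0, t0]))
    return out


def _v_richards(p, x):
    a, b, c, d = p
    return a / np.power(1.0 + _safe_exp(b - c * x), 1.0 / d)


def _lim_richards(p):
    a, b, c, d = p
    if c > 0:
        lo = a / (1.0 + math.exp(min(b, _EXP_CAP))) ** (1.0 / d)
        return (lo, a)
    if c < 0:
        hi = a / (1.0 + math.exp(min(b, _EXP_CAP))) ** (1.0 / d)
        return (a, hi)
    const = a / (1.0 + math.exp(min(b, _EXP_CAP))) ** (1.0 / d)
    return (const, const)


def _s_richards(x, y):
    a0 = float(np.max(y)) * 1.05
    out = []
    for c0 in (0.3, 0.9, 1.8):
        for b0 in (1.0, 3.0, 6.0):
            for d0 in (0.5, 1.0, 4.0):
                out.append(np.array([a0, b0, c0, d0]))
    return out


def _v_logistic(p, x):
    a, b, c = p
    return a / (1.0 + b * _safe_exp(-c * x))


def _lim_logistic(p):
    a, b, c = p
    if c > 0:
        return (a / (1.0 + b), a)
    if c < 0:
        return (a, a / (1.0 + b))
    const = a / (1.0 + b)
    return (const, const)


def _s_logistic(x, y):
    a0 = float(np.max(y)) * 1.05
    y0 = max(float(y[np.argmin(x)]), 1e-6)
    b0 = max(a0 / y0 - 1.0, 0.1)
    return [np.array([a0, b0, c0]) for c0 in (0.2, 0.6, 1.2)]


def _v_mmf(p, x):
    a, b, c, d = p
    xd = np.power(x, d)
    return (a * b + c * xd) / (b + xd)


def _lim_mmf(p):
    a, b, c, d = p
    if d > 0:
        return (a, c)
    if d < 0:
        return (c, a)
    const = (a * b + c) / (b + 1.0)
    return (const, const)


def _s_mmf(x, y):
    a0 = float(y[np.argmin(x)])
    c0 = float(y[np.argmax(x)])
    xm = float(np.median(x))
    return [np.array([a0, xm ** d0, c0, d0]) for d0 in (1.0, 2.0, 5.0)]


def _v_gompertz(p, x):
    a, b, c = p
    return a * _safe_exp(-_safe_exp(b - c * x))


def _lim_gompertz(p):
    a, b, c = p
    at0 = a * math.exp(-math.exp(min(b, _EXP_CAP)))
    if c > 0:
        return (at0, a)
    if c < 0:
        return (a, at0)
    return (at0, at0)


def _s_gompertz(x, y):
    a0 = float(np.max(y)) * 1.05
    return [np.array([a0, b0, c0]) for b0 in (0.5, 1.5, 3.0) for c0 in (0.3, 0.8)]


def _v_exp_assoc2(p, x):
    a, b, c = p
    return a * (b - _safe_exp(-c * x))


def _lim_exp_assoc2(p):
    a, b, c = p
    if c > 0:
        return (a * (b - 1.0), a * b)
    if c < 0:
        return (a * (b - 1.0), -_sign_inf(a))
    const = a * (b - 1.0)
    return (const, const)


def _s_exp_assoc2(x, y):
    yinf = float(y[np.argmax(x)])
    y0 = float(y[np.argmin(x)])
    a0 = max(yinf - y0, 1e-3)
    b0 = yinf / a0
    return [np.array([a0, b0, c0]) for c0 in (0.2, 0.6, 1.5)]


def _v_quadratic(p, x):
    a, b, c = p
    return a + x * (b + c * x)


def _d_quadratic(p, x):
    _, b, c = p
    return b + 2 * c * x


def _lim_quadratic(p):
    a, b, c = p
    for coef in (c, b):
        if coef != 0:
            return (a, _sign_inf(coef))
    return (a, a)


def _s_quadratic(x, y):
    return [np.polyfit(x, y, 2)[::-1]]


def _v_cosine(p, x):
    a, b, c, d = p
    return a + b * np.cos(c * x + d)


def _lim_cosine(p):
    a, b, c, d = p
    lo = a + b * math.cos(d)
    if b == 0 or c == 0:
        return (lo, lo)
    return (lo, math.nan)  # oscillates: no limit at infinity


def _s_cosine(x, y):
    a0 = float(np.mean(y))
    b0 = (float(np.max(y)) - float(np.min(y))) / 2.0 or 1.0
    return [
        np.array([a0, b0, c0, d0])
        for c0 in (0.05, 0.15, 0.4, 0.8)
        for d0 in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)
    ]


def _v_exp_assoc1(p, x):
    a, b = p
    return a * (1.0 - _safe_exp(-b * x))


def _lim_exp_assoc1(p):
    a, b = p
    if b > 0:
        return (0.0, a)
    if b < 0:
        return (0.0, -_sign_inf(a))
    return (0.0, 0.0)


def _s_exp_assoc1(x, y):
    a0 = float(np.max(y)) * 1.05
    return [np.array([a0, b0]) for b0 in (0.1, 0.4, 1.0)]


def _v_gaussian(p, x):
    a, b, c = p
    z = (x - b) / c
    return a * _safe_exp(-0.5 * z * z)


def _lim_gaussian(p):
    a, b, c = p
    return (a * math.exp(max(-0.5 * (b / c) ** 2, -_EXP_CAP)), 0.0)


def _s_gaussian(x, y):
    a0 = float(np.max(y))
    b0 = float(x[np.argmax(y)])
    c0 = (float(np.max(x)) - float(np.min(x))) / 4.0 or 1.0
    return [np.array([a0, b0, c0]), np.array([a0, b0 * 1.5, c0 * 2])]


def _v_inv_quadratic(p, x):
    a, b, c = p
    return 1.0 / (a + x * (b + c * x))


def _lim_inv_quadratic(p):
    a, b, c = p
    lo = 1.0 / a if a != 0 else INF
    if c != 0 or b != 0:
        hi = 0.0
    else:
        hi = lo
    return (lo, hi)


def _s_inv_quadratic(x, y):
    mask = np.abs(y) > 1e-12
    coef = np.polyfit(x[mask], 1.0 / y[mask], 2)[::-1]
    return [coef]


def _v_hyperbolic(p, x):
    a, b = p
    return a + b / x


def _lim_hyperbolic(p):
    a, b = p
    lo = _sign_inf(b) if b != 0 else a
    return (lo, a)


def _s_hyperbolic(x, y):
    A = np.column_stack([np.ones_like(x), 1.0 / x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return [coef]


def _v_exp_over_x(p, x):
    a, b = p
    return a * _safe_exp(b / x)


def _lim_exp_over_x(p):
    a, b = p
    if b < 0:
        lo = 0.0
    elif b > 0:
        lo = _sign_inf(a)
    else:
        lo = a
    return (lo, a)


def _s_exp_over_x(x, y):
    mask = y > 0
    if mask.sum() >= 2:
        A = np.column_stack([np.ones(mask.sum()), 1.0 / x[mask]])
        coef, *_ = np.linalg.lstsq(A, np.log(y[mask]), rcond=None)
        return [np.array([math.exp(coef[0]), coef[1]])]
    return [np.array([1.0, -1.0])]


def _v_root(p, x):
    a, b = p
    return a * _safe_exp(np.log(b) / x)


def _lim_root(p):
    a, b = p
    if b < 1:
        lo = 0.0
    elif b == 1:
        lo = a
    else:
        lo = _sign_inf(a)
    return (lo, a)


def _s_root(x, y):
    mask = y > 0
    if mask.sum() >= 2:
        A = np.column_stack([np.ones(mask.sum()), 1.0 / x[mask]])
        coef, *_ = np.linalg.lstsq(A, np.log(y[mask]), rcond=None)
        return [np.array([math.exp(coef[0]), math.exp(coef[1])])]
    return [np.array([1.0, 0.5])]


def _v_saturation(p, x):
    a, b = p
    return a * x / (b + x)


def _lim_saturation(p):
    a, b = p
    return (0.0, a)


def _s_saturation(x, y):
    a0 = float(np.max(y)) * 1.1
    b0 = float(np.median(x))
    return [np.array([a0, b0]), np.array([a0, b0 / 4])]


def _v_inv_power(p, x):
    a, b, c = p
    return 1.0 / (a + b * np.power(x, c))


def _lim_inv_power(p):
    a, b, c = p
    # registered with c > 0
    lo = 1.0 / a if a != 0 else INF
    hi = 0.0 if b != 0 else lo
    return (lo, hi)


def _s_inv_power(x, y):
    mask = np.abs(y) > 1e-12
    out = []
    for c0 in (0.5, 1.0, 1.4, 2.0):
        A = np.column_stack([np.ones(mask.sum()), np.power(x[mask], c0)])
        coef, *_ = np.linalg.lstsq(A, 1.0 / y[mask], rcond=None)
        out.append(np.array([coef[0], coef[1], c0]))
    return out


def _v_recip_power(p, x):
    a, b, c = p
    return np.power(a + b * x, -1.0 / c)


def _lim_recip_power(p):
    a, b, c = p
    # registered with a > 0, c > 0
    lo = a ** (-1.0 / c)
    hi = 0.0 if b > 0 else (INF if b < 0 else lo)
    return (lo, hi)


def _s_recip_power(x, y):
    mask = y > 0
    out = []
    for c0 in (0.3, 0.5, 1.0, 2.0):
        A = np.column_stack([np.ones(mask.sum()), x[mask]])
        coef, *_ = np.linalg.lstsq(A, np.power(y[mask], -c0), rcond=None)
        out.append(np.array([max(coef[0], 1e-6), coef[1], c0]))
    return out


# ---------------------------------------------------------------------------
# registration — population ranking order first, then single-plant-only
# ---------------------------------------------------------------------------

P = frozenset({"population"})
S = frozenset({"single_plant"})
PS = P | S

_register(CurveModel(
    id="cubic", formula_text="y = a + b*x + c*x^2 + d*x^3",
    param_names=("a", "b", "c", "d"), value=_v_cubic, deriv=_d_cubic,
    limits=_lim_cubic, start_candidates=_s_cubic,
    bounds=(FREE, FREE, FREE, FREE), roles=PS))

_register(CurveModel(
    id="rational", formula_text="y = (a + b*x) / (1 + c*x + d*x^2)",
    param_names=("a", "b", "c", "d"), value=_v_rational,
    limits=_lim_rational, start_candidates=_s_rational,
    bounds=(FREE, FREE, FREE, FREE), roles=PS))

_register(CurveModel(
    id="hoerl", formula_text="y = a * b^x * x^c",
    param_names=("a", "b", "c"), value=_v_hoerl, deriv=_d_hoerl,
    limits=_lim_hoerl, start_candidates=_s_hoerl,
    bounds=(POS, (0.0, 1.0), POS), roles=P,
    notes="Population density-response family: rises on (0, -c/ln b), "
          "falls beyond; both tails decay to zero."))

_register(CurveModel(
    id="hoerl_mod", formula_text="y = a * b^(1/x) * x^c",
    param_names=("a", "b", "c"), value=_v_hoerl_mod,
    limits=_lim_hoerl_mod, start_candidates=_s_hoerl_mod,
    bounds=(POS, POS, FREE), roles=PS))

_register(CurveModel(
    id="exp_log", formula_text="y = exp(a + b/x + c*ln(x))",
    param_names=("a", "b", "c"), value=_v_exp_log,
    limits=_lim_exp_log, start_candidates=_s_exp_log,
    bounds=(FREE, FREE, FREE), roles=PS,
    notes="Reparameterisation of a*b^(1/x)*x^c with a=e^a', b=e^b'."))

_register(CurveModel(
    id="weibull", formula_text="y = m - n * exp(-p * x^t)",
    param_names=("m", "n", "p", "t"), value=_v_weibull, deriv=_d_weibull,
    limits=_lim_weibull, start_candidates=_s_weibull,
    bounds=(FREE, FREE, POS, FREE), roles=PS,
    notes="Single-plant decline family: with p>0, t<0, n>0 it falls "
          "monotonically from m at sparse stands to m-n under crowding."))

_register(CurveModel(
    id="richards", formula_text="y = a / (1 + exp(b - c*x))^(1/d)",
    param_names=("a", "b", "c", "d"), value=_v_richards,
    limits=_lim_richards, start_candidates=_s_richards,
    bounds=(FREE, FREE, FREE, POS), roles=P,
    notes="Four-parameter sigmoid. The typeset source formula "
          "a/(1+e^(b-cx)^(1/d)) is ambiguous about what the 1/d exponent "
          "applies to; this implementation uses the standard Richards "
          "reading with the outer bracket raised to 1/d."))

_register(CurveModel(
    id="logistic", formula_text="y = a / (1 + b * exp(-c*x))",
    param_names=("a", "b", "c"), value=_v_logistic,
    limits=_lim_logistic, start_candidates=_s_logistic,
    bounds=(FREE, POS, FREE), roles=P))

_register(CurveModel(
    id="mmf", formula_text="y = (a*b + c*x^d) / (b + x^d)",
    param_names=("a", "b", "c", "d"), value=_v_mmf,
    limits=_lim_mmf, start_candidates=_s_mmf,
    bounds=(FREE, POS, FREE, FREE), roles=P,
    notes="Morgan-Mercer-Flodin sigmoid."))

_register(CurveModel(
    id="gompertz", formula_text="y = a * exp(-exp(b - c*x))",
    param_names=("a", "b", "c"), value=_v_gompertz,
    limits=_lim_gompertz, start_candidates=_s_gompertz,
    bounds=(FREE, FREE, FREE), roles=P))

_register(CurveModel(
    id="exp_assoc2", formula_text="y = a * (b - exp(-c*x))",
    param_names=("a", "b", "c"), value=_v_exp_assoc2,
    limits=_lim_exp_assoc2, start_candidates=_s_exp_assoc2,
    bounds=(FREE, FREE, FREE), roles=P))

_register(CurveModel(
    id="quadratic", formula_text="y = a + b*x + c*x^2",
    param_names=("a", "b", "c"), value=_v_quadratic, deriv=_d_quadratic,
    limits=_lim_quadratic, start_candidates=_s_quadratic,
    bounds=(FREE, FREE, FREE), roles=PS))

_register(CurveModel(
    id="cosine", formula_text="y = a + b*cos(c*x + d)",
    param_names=("a", "b", "c", "d"), value=_v_cosine,
    limits=_lim_cosine, start_candidates=_s_cosine,
    bounds=(FREE, FREE, FREE, FREE), roles=PS,
    notes="Oscillatory; has no limit as x -> inf unless b or c is zero."))

_register(CurveModel(
    id="exp_assoc1", formula_text="y = a * (1 - exp(-b*x))",
    param_names=("a", "b"), value=_v_exp_assoc1,
    limits=_lim_exp_assoc1, start_candidates=_s_exp_assoc1,
    bounds=(FREE, FREE), roles=P))

_register(CurveModel(
    id="gaussian", formula_text="y = a * exp(-(x - b)^2 / (2*c^2))",
    param_names=("a", "b", "c"), value=_v_gaussian,
    limits=_lim_gaussian, start_candidates=_s_gaussian,
    bounds=(FREE, FREE, POS), roles=P))

_register(CurveModel(
    id="inv_quadratic", formula_text="y = 1 / (a + b*x + c*x^2)",
    param_names=("a", "b", "c"), value=_v_inv_quadratic,
    limits=_lim_inv_quadratic, start_candidates=_s_inv_quadratic,
    bounds=(FREE, FREE, FREE), roles=PS))

_register(CurveModel(
    id="hyperbolic", formula_text="y = a + b/x",
    param_names=("a", "b"), value=_v_hyperbolic,
    limits=_lim_hyperbolic, start_candidates=_s_hyperbolic,
    bounds=(FREE, FREE), roles=P))

_register(CurveModel(
    id="exp_over_x", formula_text="y = a * exp(b/x)",
    param_names=("a", "b"), value=_v_exp_over_x,
    limits=_lim_exp_over_x, start_candidates=_s_exp_over_x,
    bounds=(FREE, FREE), roles=P))

_register(CurveModel(
    id="root", formula_text="y = a * b^(1/x)",
    param_names=("a", "b"), value=_v_root,
    limits=_lim_root, start_candidates=_s_root,
    bounds=(FREE, POS), roles=P))

_register(CurveModel(
    id="saturation", formula_text="y = a*x / (b + x)",
    param_names=("a", "b"), value=_v_saturation,
    limits=_lim_saturation, start_candidates=_s_saturation,
    bounds=(FREE, POS), roles=P,
    notes="Michaelis-Menten / saturation-growth form."))

_register(CurveModel(
    id="inv_power", formula_text="y = 1 / (a + b*x^c)",
    param_names=("a", "b", "c"), value=_v_inv_power,
    limits=_lim_inv_power, start_candidates=_s_inv_power,
    bounds=(FREE, FREE, POS), roles=S))

_register(CurveModel(
    id="recip_power", formula_text="y = (a + b*x)^(-1/c)",
    param_names=("a", "b", "c"), value=_v_recip_power,
    limits=_lim_recip_power, start_candidates=_s_recip_power,
    bounds=(POS, FREE, POS), roles=S))


POPULATION_FAMILIES: tuple[str, ...] = tuple(
    m.id for m in CATALOG.values() if "population" in m.roles
)
SINGLE_PLANT_FAMILIES: tuple[str, ...] = tuple(
    m.id for m in CATALOG.values() if "single_plant" in m.roles
)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def get_model(model_id: str) -> CurveModel:
    try:
        return CATALOG[model_id]
    except KeyError:
        raise CatalogError(
            f"unknown curve family {model_id!r}; known: {sorted(CATALOG)}"
        ) from None


def _check_x(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if not np.all(arr > 0):
        raise DensityDomainError("planting density x must be > 0")
    return arr, scalar


def evaluate(model_id: str, params: Sequence[float], x) -> np.ndarray | float:
    """Evaluate a catalog family at density ``x`` (plants m⁻²).

    Parameters are validated against the family's admissible intervals;
    evaluation is overflow-safe so that probes at extreme densities return
    0.0 / inf rather than raising.
    """
    model = get_model(model_id)
    p = model.check_params(params)
    arr, scalar = _check_x(x)
    with np.errstate(over="ignore", under="ignore", divide="ignore"):
        y = np.asarray(model.value(p, arr), dtype=float)
    return float(y[0]) if scalar else y


def derivative(model_id: str, params: Sequence[float], x,
               *, rel_step: float = 1e-6) -> np.ndarray | float:
    """dy/dx at density ``x`` (relative yield per plants m⁻²).

    Uses the family's closed form when available (for Hoerl this is
    a·bˣ·x^(c−1)·(x·ln b + c), the yield change-rate curve); otherwise a
    central finite difference with relative step ``rel_step``.
    """
    model = get_model(model_id)
    p = model.check_params(params)
    arr, scalar = _check_x(x)
    with np.errstate(over="ignore", under="ignore", divide="ignore"):
        if model.deriv is not None:
            d = np.asarray(model.deriv(p, arr), dtype=float)
        else:
            h = rel_step * arr
            d = (np.asarray(model.value(p, arr + h), dtype=float)
                 - np.asarray(model.value(p, arr - h), dtype=float)) / (2.0 * h)
    return float(d[0]) if scalar else d


def limit_behavior(model_id: str, params: Sequence[float]) -> tuple[float, float]:
    """Symbolic limits (x→0⁺, x→∞) of a family at the given parameters.

    Returns extended reals; ``math.nan`` means the limit does not exist
    (oscillatory family).  These are the quantities the biological
    plausibility screen inspects.
    """
    model = get_model(model_id)
    p = model.check_params(params)
    if model.limits is None:
        raise UnsupportedFamilyError(f"{model_id}: no symbolic limit rule coded")
    lo, hi = model.limits(tuple(p))
    return (float(lo), float(hi))


def numeric_limit_probe(model_id: str, params: Sequence[float],
                        x_small: float = 1e-8, x_large: float = 1e8,
                        ) -> tuple[float, float]:
    """Overflow-safe numeric evaluation near the two extremes.

    A sanity companion to :func:`limit_behavior`: the symbolic answer must
    not contradict these probes (tests compare them with tolerance for the
    slow approach of some families).
    """
    return (float(evaluate(model_id, params, x_small)),
            float(evaluate(model_id, params, x_large)))


def export_catalog() -> "pd.DataFrame":
    """Machine-readable listing of the catalog (one row per family).

    Columns: id, formula, n_params, param names, admissible intervals and
    role tags, in registration (printed-ranking) order.
    """
    import pandas as pd

    rows = []
    for m in CATALOG.values():
        rows.append({
            "id": m.id,
            "formula": m.formula_text,
            "n_params": m.n_params,
            "params": " ".join(m.param_names),
            "constraints": "; ".join(
                f"{nm} in ({lo}, {hi})" for nm, (lo, hi)
                in zip(m.param_names, m.bounds) if (lo, hi) != FREE
            ) or "none",
            "roles": "+".join(sorted(m.roles)),
            "closed_derivative": m.has_closed_derivative,
        })
    return pd.DataFrame(rows)
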