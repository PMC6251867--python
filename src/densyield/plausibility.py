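"""Biological plausibility screening of fitted density-response curves.

A family can fit the data well yet imply nonsense biology.  For population
(per-area) relative yield the screen demands what crowding biology demands:
yield vanishes both when the stand is extremely sparse (x→0⁺) and when it
is extremely dense (x→∞), with a single interior optimum in between.  A
cubic polynomial diverges at high density and a rational function keeps a
nonzero yield at zero density, so both are rejected regardless of their
(slightly better) fit statistics, leaving the Hoerl family as the selected
population model.

For single-plant relative yield the screen codifies a bounded, monotone
decline over the design density range toward a finite non-negative
asymptote; the source study asserts only that the Weibull-type decline is
the suitable family, so these criteria are this package's explicit reading
(documented, not claimed as the original procedure).

Screening is a pure function of family + parameters; it never looks at the
data that produced the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import evaluate, derivative, get_model, limit_behavior
from .errors import UnsupportedFamilyError
from .fitting import FitResult

__all__ = [
    "Verdict",
    "SelectionResult",
    "screen_population",
    "screen_single_plant",
    "select_model",
]

#: Design density range (plants m⁻²) over which single-plant decline is
#: required; matches the gradient trial design.
DESIGN_RANGE: tuple[float, float] = (1.67, 16.67)

_UNIMODAL_GRID = np.geomspace(1e-3, 1e3, 1000)


@dataclass(frozen=True)
class Verdict:
    """Outcome of a plausibility screen."""

    plausible: bool
    reasons: tuple[str, ...] = ()  # empty when plausible

    def __bool__(self) -> bool:
        return self.plausible


@dataclass(frozen=True)
class SelectionResult:
    """Best-ranked fit passing the screen, plus an audit of rejections."""

    selected: FitResult | None
    rejected: tuple[tuple[FitResult, Verdict], ...] = ()

    @property
    def n_rejected_above(self) -> int:
        """How many better-ranked fits failed the screen."""
        return len(self.rejected)


def _interior_maximum_count(model_id: str, params: Sequence[float]) -> int:
    """Count +→− sign changes of dy/dx on a log grid over [1e−3, 1e3].

    For the Hoerl family this is resolved analytically: with a>0, 0<b<1,
    c>0 the derivative a·bˣ·x^(c−1)(x·ln b + c) changes sign exactly once,
    at x* = −c/ln b.
    """
    if model_id == "hoerl":
        return 1  # admissibility (0<b<1, c>0) guarantees one interior max
    with np.errstate(all="ignore"):
        d = np.asarray(derivative(model_id, params, _UNIMODAL_GRID))
    sign = np.sign(d[np.isfinite(d)])
    sign = sign[sign != 0]
    if sign.size < 2:
        return 0
    flips = np.flatnonzero(np.diff(sign))
    return int(np.sum(sign[flips] > 0))  # + -> - transitions only


def _any_sign_change(model_id: str, params: Sequence[float]) -> int:
    if model_id == "hoerl":
        return 1
    with np.errstate(all="ignore"):
        d = np.asarray(derivative(model_id, params, _UNIMODAL_GRID))
    sign = np.sign(d[np.isfinite(d)])
    sign = sign[sign != 0]
    return int(np.sum(np.diff(sign) != 0)) if sign.size else 0


def screen_population(fit: FitResult) -> Verdict:
    """Screen a population-yield fit for density-response biology.

    Plausible iff lim x→0⁺ y = 0, lim x→∞ y = 0, and the curve has a single
    interior maximum on (0, ∞).  Reasons enumerate every failed criterion.
    """
    get_model(fit.model_id)  # raises CatalogError for unknown families
    lo, hi = limit_behavior(fit.model_id, fit.params)  # may raise Unsupported
    reasons: list[str] = []
    if math.isnan(lo):
        reasons.append("no limit as x->0+ (oscillatory)")
    elif lo != 0.0:
        reasons.append(
            "nonzero yield at zero density"
            if math.isfinite(lo) else "diverges as x->0+"
        )
    if math.isnan(hi):
        reasons.append("no limit as x->inf (oscillatory)")
    elif hi != 0.0:
        reasons.append(
            "nonzero yield at unbounded density"
            if math.isfinite(hi) else "diverges as x->inf"
        )
    n_max = _interior_maximum_count(fit.model_id, fit.params)
    if n_max != 1:
        reasons.append(f"{n_max} interior maxima on (0, inf); need exactly 1")
    elif _any_sign_change(fit.model_id, fit.params) != 1:
        reasons.append("derivative changes sign more than once (not unimodal)")
    return Verdict(plausible=not reasons, reasons=tuple(reasons))


def screen_single_plant(fit: FitResult) -> Verdict:
    """Screen a single-plant-yield fit.

    Plausible iff the curve is bounded and non-increasing across the design
    density range and approaches a finite non-negative asymptote as x→∞.
    """
    get_model(fit.model_id)
    _, hi = limit_behavior(fit.model_id, fit.params)
    reasons: list[str] = []
    if math.isnan(hi):
        reasons.append("no limit as x->inf (oscillatory)")
    elif not math.isfinite(hi):
        reasons.append("unbounded as x->inf")
    elif hi < 0:
        reasons.append(f"negative asymptotic yield ({hi:.4g}) as x->inf")
    grid = np.linspace(DESIGN_RANGE[0], DESIGN_RANGE[1], 200)
    with np.errstate(all="ignore"):
        vals = np.asarray(evaluate(fit.model_id, fit.params, grid))
        d = np.asarray(derivative(fit.model_id, fit.params, grid))
    if not np.all(np.isfinite(vals)):
        reasons.append("unbounded on the design density range")
    # tolerance absorbs finite-difference noise on flat stretches
    if np.any(d > 1e-8 * max(1.0, float(np.nanmax(np.abs(vals))))):
        reasons.append("increasing somewhere on the design density range")
    return Verdict(plausible=not reasons, reasons=tuple(reasons))


def select_model(ranked_fits: Sequence[FitResult],
                 screen=screen_population) -> SelectionResult:
    """Return the highest-ranked fit that passes ``screen``.

    Better-ranked rejected fits are reported with their verdicts.  If no fit
    passes (or the list is empty) the result carries ``selected=None`` —
    an explicit no-selection outcome, not an exception.
    """
    rejected: list[tuple[FitResult, Verdict]] = []
    for f in ranked_fits:
        if not f.converged:
            rejected.append((f, Verdict(False, ("fit did not converge",))))
            continue
        try:
            verdict = screen(f)
        except UnsupportedFamilyError as exc:
            rejected.append((f, Verdict(False, (str(exc),))))
            continue
        if verdict.plausible:
            return SelectionResult(selected=f, rejected=tuple(rejected))
        rejected.append((f, verdict))
    return SelectionResult(selected=None, rejected=tuple(rejected))
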