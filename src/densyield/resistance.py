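"""Density-resistance analytics.

Once a plausible Hoerl fit ``y = a·bˣ·xᶜ`` describes a variety's population
relative yield, its density resistance is summarised by closed-form
quantities: the optimal planting density x* = −c/ln b (where the yield
change rate a·bˣ·x^(c−1)(x·ln b + c) crosses zero), the peak relative
yield y(x*), and the ranking of varieties by descending x*.  Single-plant
tolerance is summarised by the average decline rate of the Weibull curve
over the design range (endpoint secant).

The module also carries the trial-design arithmetic (row spacing →
density under alternating wide/narrow line spacing), the normalisation of
raw yields to the reference (lowest) density, and verification of a fitted
model against conventional fixed-density standard plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import HoerlParams, WeibullParams, evaluate
from .errors import (
    DensityDomainError,
    InsufficientDataError,
    NormalizationError,
)
from .fitting import FitResult

__all__ = [
    "ResistanceReport",
    "VerificationResult",
    "normalize",
    "optimal_density",
    "peak_relative_yield",
    "change_rate",
    "resistance_ranking",
    "single_plant_decline",
    "spacing_to_density",
    "percent_deviation",
    "verify_against_standard",
    "grid_argmax",
]

HoerlLike = HoerlParams | Sequence[float]
WeibullLike = WeibullParams | Sequence[float]


def _hoerl(params: HoerlLike) -> HoerlParams:
    if isinstance(params, HoerlParams):
        return params
    return HoerlParams(*params)


def _weibull(params: WeibullLike) -> WeibullParams:
    if isinstance(params, WeibullParams):
        return params
    return WeibullParams(*params)


@dataclass(frozen=True)
class ResistanceReport:
    """Per-variety density-resistance summary."""

    label: str
    params: HoerlParams
    optimal_density: float       # x* = -c/ln b, plants m^-2
    peak_relative_yield: float   # y(x*)
    rank: int = 0                # 1 = most density-resistant

    def change_rate(self, x) -> float | np.ndarray:
        return change_rate(self.params, x)


@dataclass(frozen=True)
class VerificationResult:
    """Regression of measured standard-plot yields on simulated yields."""

    slope: float
    intercept: float
    accuracy: float                       # squared correlation, in [0, 1]
    deviations: tuple[tuple[float, float], ...]  # (density, % deviation)
    reference_density: float
    reference_yield: float

    @property
    def mean_abs_deviation(self) -> float:
        return float(np.mean([abs(d) for _, d in self.deviations]))


# ---------------------------------------------------------------------------
# normalisation and design arithmetic
# ---------------------------------------------------------------------------

def normalize(table: pd.DataFrame, reference: str | float = "min",
              *, group_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Scale yields so the reference-density group mean equals 1.

    ``reference`` is ``"min"`` (lowest density present per group, the
    default), ``"fixed:<density>"`` or a numeric density.  Grouping defaults
    to whichever of ``variety``/``year`` columns are present, so the
    normalisation removes scale differences between varieties and years.
    """
    if "density" not in table.columns or "yield" not in table.columns:
        raise NormalizationError("table must have density and yield columns")
    if isinstance(reference, str) and reference.startswith("fixed:"):
        reference = float(reference.split(":", 1)[1])

    if group_cols is None:
        group_cols = [c for c in ("variety", "year") if c in table.columns]

    def _scale(group: pd.DataFrame) -> pd.DataFrame:
        dens = group["density"].to_numpy(dtype=float)
        if reference == "min":
            ref = float(dens.min())
        else:
            ref = float(reference)
            if not np.any(np.isclose(dens, ref)):
                key = (tuple(group.iloc[0][c] for c in group_cols)
                       if group_cols else "<all>")
                raise NormalizationError(
                    f"reference density {ref} absent from group {key}"
                )
        at_ref = group.loc[np.isclose(dens, ref), "yield"]
        mean_ref = float(at_ref.mean())
        if mean_ref == 0:
            raise NormalizationError("reference-density mean yield is zero")
        out = group.copy()
        out["yield"] = out["yield"] / mean_ref
        return out

    if group_cols:
        parts = [_scale(g) for _, g in table.groupby(list(group_cols), sort=False)]
        return pd.concat(parts, ignore_index=True)
    return _scale(table).reset_index(drop=True)


def spacing_to_density(row_spacing_cm: float,
                       line_spacings_cm: tuple[float, float] = (80.0, 40.0),
                       ) -> float:
    """Plants m⁻² for one plant per grid position.

    density = 1 / (mean line spacing [m] × row spacing [m]).  The default
    alternating 80/40 cm lines give the trial's mean 60 cm line spacing.
    """
    if row_spacing_cm <= 0 or any(s <= 0 for s in line_spacings_cm):
        raise DensityDomainError("spacings must be positive")
    mean_line_m = (line_spacings_cm[0] + line_spacings_cm[1]) / 2.0 / 100.0
    return 1.0 / (mean_line_m * row_spacing_cm / 100.0)


# ---------------------------------------------------------------------------
# Hoerl-derived quantities
# ---------------------------------------------------------------------------

def optimal_density(params: HoerlLike) -> float:
    """Optimal planting density x* = −c/ln b (plants m⁻²).

    The stationary point of the Hoerl curve: the density at which the yield
    change rate crosses zero and population yield peaks.  Higher x* means
    greater density resistance.
    """
    p = _hoerl(params)  # validates 0<b<1, c>0
    return -p.c / math.log(p.b)


def peak_relative_yield(params: HoerlLike) -> float:
    p = _hoerl(params)
    return float(evaluate("hoerl", p.as_tuple(), optimal_density(p)))


def change_rate(params: HoerlLike, x) -> float | np.ndarray:
    """Rate of change of population relative yield, a·bˣ·x^(c−1)(x·ln b + c).

    Positive below the optimal density, zero at it, negative above.
    """
    p = _hoerl(params)
    from .catalog import derivative

    return derivative("hoerl", p.as_tuple(), x)


def grid_argmax(params: HoerlLike, upper: float = 50.0,
                step: float = 1e-4) -> float:
    """Brute-force argmax of the Hoerl curve on (0, upper] — the
    independent oracle for :func:`optimal_density`."""
    p = _hoerl(params)
    xs = np.arange(step, upper + step, step)
    ys = evaluate("hoerl", p.as_tuple(), xs)
    return float(xs[int(np.argmax(ys))])


def resistance_ranking(
    fits: Mapping[str, HoerlLike] | Sequence[tuple[str, HoerlLike]] | Sequence[FitResult],
) -> list[ResistanceReport]:
    """Rank varieties by descending optimal density (density resistance).

    Accepts a mapping label→Hoerl params, (label, params) pairs, or
    labelled Hoerl :class:`FitResult` objects.  Ties break by peak relative
    yield, then label.  Non-Hoerl fits raise ``TypeError``.
    """
    items: list[tuple[str, HoerlParams]] = []
    if isinstance(fits, Mapping):
        pairs = list(fits.items())
    else:
        pairs = []
        for entry in fits:
            if isinstance(entry, FitResult):
                if entry.model_id != "hoerl":
                    raise TypeError(
                        f"resistance ranking needs Hoerl fits, got "
                        f"{entry.model_id!r} for {entry.label!r}"
                    )
                pairs.append((entry.label, entry.params))
            else:
                pairs.append(entry)
    for label, params in pairs:
        items.append((str(label), _hoerl(params)))

    reports = [
        ResistanceReport(
            label=label,
            params=p,
            optimal_density=optimal_density(p),
            peak_relative_yield=peak_relative_yield(p),
        )
        for label, p in items
    ]
    reports.sort(key=lambda r: (-r.optimal_density, -r.peak_relative_yield,
                                r.label))
    return [ResistanceReport(r.label, r.params, r.optimal_density,
                             r.peak_relative_yield, rank=i + 1)
            for i, r in enumerate(reports)]


# ---------------------------------------------------------------------------
# single-plant decline
# ---------------------------------------------------------------------------

def single_plant_decline(params: WeibullLike,
                         density_range: tuple[float, float] = (1.67, 16.67),
                         ) -> float:
    """Average decline rate of single-plant relative yield over a range.

    Endpoint secant (y(x_low) − y(x_high)) / (x_high − x_low), in relative
    yield per plants m⁻²; non-negative for monotone-declining fits.  Higher
    values mean the variety sheds per-plant yield faster under crowding.
    """
    lo, hi = density_range
    if not (0 < lo < hi):
        raise DensityDomainError(
            f"degenerate density interval ({lo}, {hi}); need 0 < low < high"
        )
    p = _weibull(params)
    y_lo = float(evaluate("weibull", p.as_tuple(), lo))
    y_hi = float(evaluate("weibull", p.as_tuple(), hi))
    return (y_lo - y_hi) / (hi - lo)


# ---------------------------------------------------------------------------
# verification against standard plots
# ---------------------------------------------------------------------------

def percent_deviation(standard_yield: float, gradient_yield: float) -> float:
    """Percent deviation of the gradient-method yield from the standard
    plot: 100·(gradient − standard)/standard, rounded to 2 decimals."""
    if standard_yield <= 0:
        raise DensityDomainError("standard yield must be positive")
    return round(100.0 * (gradient_yield - standard_yield) / standard_yield, 2)


def verify_against_standard(fit: FitResult | HoerlLike,
                            standard: pd.DataFrame,
                            *, reference: str | float = "min",
                            ) -> VerificationResult:
    """Compare model-simulated yields with measured standard-plot yields.

    The fitted relative-yield curve is rescaled to absolute g m⁻² using the
    standard plot's mean yield at the reference density, then measured is
    regressed on simulated by ordinary least squares.  ``accuracy`` is the
    squared correlation; per-density percent deviations use
    :func:`percent_deviation` (simulated vs measured).
    """
    if isinstance(fit, FitResult):
        model_id, params = fit.model_id, fit.params
    else:
        model_id, params = "hoerl", _hoerl(fit).as_tuple()

    means = (standard.groupby("density", as_index=False)["yield"].mean()
             .sort_values("density"))
    dens = means["density"].to_numpy(dtype=float)
    measured = means["yield"].to_numpy(dtype=float)
    if dens.size < 3:
        raise InsufficientDataError(
            f"verification needs >=3 densities, found {dens.size}"
        )
    if isinstance(reference, str) and reference.startswith("fixed:"):
        reference = float(reference.split(":", 1)[1])
    ref_density = float(dens.min()) if reference == "min" else float(reference)
    sel = np.isclose(dens, ref_density)
    if not sel.any():
        raise NormalizationError(
            f"reference density {ref_density} absent from standard plot"
        )
    ref_yield = float(measured[sel][0])

    rel = np.asarray(evaluate(model_id, params, dens), dtype=float)
    rel_ref = float(evaluate(model_id, params, ref_density))
    simulated = rel / rel_ref * ref_yield

    reg = stats.linregress(simulated, measured)
    deviations = tuple(
        (float(d), percent_deviation(m, s))
        for d, m, s in zip(dens, measured, simulated)
    )
    return VerificationResult(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        accuracy=float(reg.rvalue) ** 2,
        deviations=deviations,
        reference_density=ref_density,
        reference_yield=ref_yield,
    )


def resistance_report_frame(reports: Sequence[ResistanceReport]) -> pd.DataFrame:
    """Delimited-text-ready resistance report (4-decimal rounding)."""
    return pd.DataFrame([
        {
            "rank": r.rank,
            "variety": r.label,
            "a": round(r.params.a, 4),
            "b": round(r.params.b, 4),
            "c": round(r.params.c, 4),
            "optimal_density": round(r.optimal_density, 4),
            "peak_relative_yield": round(r.peak_relative_yield, 4),
        }
        for r in reports
    ])
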