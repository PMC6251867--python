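"""Ear-trait and plant-morphology analytics.

Crowding stress reshapes the maize ear and plant long before it shows in
yield: ear length, ear perimeter and thousand-kernel weight shrink with
density, bald-tip length grows, and prolificacy (double ears) collapses to
zero beyond a few plants m⁻².  This module provides the descriptive
statistics used to characterise those responses: a pairwise-complete
Pearson correlation matrix with significance stars, double-ear occurrence
profiles, and morphological-index ratios evaluated at a variety's optimal
density.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DensityDomainError, ValidationError
from .fitting import significance_stars

__all__ = [
    "TRAIT_COLUMNS",
    "pearson_matrix",
    "double_ear_profile",
    "morphology_at_optimum",
]

#: Canonical trait-table column names (delimited-text header contract).
TRAIT_COLUMNS: tuple[str, ...] = (
    "variety", "density",
    "ear_length", "bald_tip_length", "ear_perimeter",
    "ears_per_area", "grains_per_area", "thousand_kernel_weight",
    "plant_yield", "area_yield",
    "plant_height", "ear_height", "stem_diameter", "double_ear",
)


def pearson_matrix(table: pd.DataFrame, columns: Sequence[str],
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with significance stars.

    Returns ``(r, stars)`` DataFrames indexed by ``columns``.  Each pair is
    computed over rows where both traits are present (pairwise-complete,
    since trait availability varies by year); stars use the two-sided
    t-test with that pair's n − 2 df.  A constant column yields NaN entries
    (flagged, not silently zero) and requires n ≥ 3 complete rows per pair.
    """
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValidationError(f"trait table missing columns {missing}")
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns, dtype=float)
    stars = pd.DataFrame("", index=columns, columns=columns, dtype=object)
    for i in range(k):
        for j in range(i + 1, k):
            a = pd.to_numeric(table[columns[i]], errors="coerce")
            b = pd.to_numeric(table[columns[j]], errors="coerce")
            mask = a.notna() & b.notna()
            n = int(mask.sum())
            if n < 3:
                raise ValidationError(
                    f"pair ({columns[i]}, {columns[j]}) has only {n} "
                    "complete records; need >= 3"
                )
            av = a[mask].to_numpy(dtype=float)
            bv = b[mask].to_numpy(dtype=float)
            if np.ptp(av) == 0 or np.ptp(bv) == 0:
                rij, mark = math.nan, "undefined"
            else:
                rij = float(np.corrcoef(av, bv)[0, 1])
                mark = significance_stars(rij, n)
            r.iloc[i, j] = r.iloc[j, i] = rij
            stars.iloc[i, j] = stars.iloc[j, i] = mark
    return r, stars


def double_ear_profile(table: pd.DataFrame,
                       densities: Sequence[float] | None = None,
                       ) -> pd.DataFrame:
    """Double-ear occurrence rate (%) per variety per density.

    Expects per-plant records with a 0/1 (or bool) ``double_ear`` flag.
    Returns a variety × density frame of 100·(double-ear plants / plants
    observed); density groups with no observations are missing values
    (NaN), never zero.
    """
    for col in ("variety", "density", "double_ear"):
        if col not in table.columns:
            raise ValidationError(f"per-plant table missing column {col!r}")
    rates = (
        table.assign(double_ear=table["double_ear"].astype(float))
        .groupby(["variety", "density"])["double_ear"]
        .mean()
        .mul(100.0)
        .unstack("density")
    )
    if densities is not None:
        rates = rates.reindex(columns=list(densities))
    return rates


def morphology_at_optimum(trajectories: pd.DataFrame, x_star: float,
                          ) -> dict[str, float]:
    """Morphological-index ratios at the optimal density.

    ``trajectories`` holds per-density means with columns ``density``,
    ``plant_height``, ``ear_height``, ``stem_diameter`` and
    ``plant_yield``; values at x* are obtained by linear interpolation
    between adjacent measured densities.

    Returns ratios that characterise the crop at its optimum:
    ``height_ratio`` (plant height at x* / max height over the
    trajectory), ``ear_plant_ratio`` (ear height / plant height at x*),
    ``stem_ratio`` (stem diameter at x* / at the lowest density) and
    ``yield_ratio`` (single-plant yield at x* / max single-plant yield).
    """
    need = ("density", "plant_height", "ear_height", "stem_diameter",
            "plant_yield")
    missing = [c for c in need if c not in trajectories.columns]
    if missing:
        raise ValidationError(f"trajectory table missing columns {missing}")
    traj = trajectories.sort_values("density")
    dens = traj["density"].to_numpy(dtype=float)
    if not (dens.min() <= x_star <= dens.max()):
        raise DensityDomainError(
            f"optimal density {x_star:.4g} outside measured trajectory "
            f"range [{dens.min():.4g}, {dens.max():.4g}]; refusing to "
            "extrapolate"
        )

    def at_opt(col: str) -> float:
        return float(np.interp(x_star, dens, traj[col].to_numpy(dtype=float)))

    height = at_opt("plant_height")
    return {
        "height_ratio": height / float(traj["plant_height"].max()),
        "ear_plant_ratio": at_opt("ear_height") / height,
        "stem_ratio": at_opt("stem_diameter")
        / float(traj["stem_diameter"].iloc[0]),
        "yield_ratio": at_opt("plant_yield")
        / float(traj["plant_yield"].max()),
    }
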