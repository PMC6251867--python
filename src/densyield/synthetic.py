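"""Synthetic maize density-gradient trial generator.

The original five-year field records were never deposited, so every stage
of the pipeline is exercised on simulated trials that carry the same
statistical structure the analysis assumes: population relative yield
follows a variety-specific Hoerl curve and single-plant relative yield a
variety-specific Weibull decline (both seeded from the published fits),
with additive Gaussian noise at the scale of the published fit standard
errors, a multiplicative shared-year effect (removed exactly by the
normalisation stage), density-decaying double-ear occurrence, and ear /
morphology trait means that drift linearly in log density between
realistic endpoints.

What this emulates — and what it does not — is spelled out in the methods
note: the generator reproduces curve shapes, noise magnitudes and ordinal
trait behaviour, not field spatial structure, weather, or genotype × year
interaction beyond a scalar year effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference as ref
from .catalog import evaluate
from .errors import ValidationError

__all__ = [
    "VarietyTruth",
    "MorphologyTruth",
    "SyntheticTruth",
    "default_truth",
    "simulate_gradient_trial",
    "simulate_standard_plot",
    "simulate_trait_table",
    "DEFAULT_TRAIT_CORR",
    "TRAIT_CORR_COLUMNS",
]


@dataclass(frozen=True)
class VarietyTruth:
    """Generative parameters for one variety."""

    hoerl: tuple[float, float, float]            # population relative yield
    weibull: tuple[float, float, float, float]   # single-plant relative yield
    pop_noise_sd: float                          # on the relative-yield scale
    plant_noise_sd: float
    double_ear_rates: tuple[float, ...]          # %, aligned with densities
    max_plant_height: float = 270.0              # cm


@dataclass(frozen=True)
class MorphologyTruth:
    """Shared morphology-trajectory parameters.

    Plant height approaches its maximum as competition for light stiffens:
    h(x) = H·(1 − height_deficit·e^(−height_rate·x)).  The ear/plant height
    ratio rises linearly in log density between ``ear_ratio_range``
    endpoints; stem diameter tapers by ``stem_taper`` of its low-density
    value across the design range.
    """

    height_deficit: float = 0.30
    height_rate: float = 0.40        # per plants m^-2
    ear_ratio_range: tuple[float, float] = (0.40, 0.50)
    stem_base_cm: float = 2.2
    stem_taper: float = 0.35
    ear_length_range: tuple[float, float] = (20.0, 14.5)    # cm, low->high x
    bald_tip_range: tuple[float, float] = (0.4, 2.8)        # cm
    ear_perimeter_range: tuple[float, float] = (16.0, 13.2)  # cm
    tkw_range: tuple[float, float] = (340.0, 255.0)         # g


@dataclass(frozen=True)
class SyntheticTruth:
    """Complete generative parameter set for a simulated trial."""

    varieties: Mapping[str, VarietyTruth]
    densities: tuple[float, ...] = ref.DESIGN_DENSITIES
    reference_yield: float = 800.0        # g m^-2 at relative yield 1
    plant_yield_scale: float = 320.0      # g per plant at relative yield 1
    year_offset_sd: float = 0.02          # multiplicative shared-year effect
    morphology: MorphologyTruth = field(default_factory=MorphologyTruth)
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.reference_yield <= 0 or self.plant_yield_scale <= 0:
            problems.append("yield scales must be positive")
        if self.year_offset_sd < 0:
            problems.append("year_offset_sd must be >= 0")
        if any(d <= 0 for d in self.densities):
            problems.append("densities must be positive")
        for name, vt in self.varieties.items():
            a, b, c = vt.hoerl
            if not (a > 0 and 0 < b < 1 and c > 0):
                problems.append(f"{name}: inadmissible Hoerl params {vt.hoerl}")
            if not vt.weibull[2] > 0:
                problems.append(f"{name}: Weibull p must be > 0")
            if vt.pop_noise_sd < 0 or vt.plant_noise_sd < 0:
                problems.append(f"{name}: noise sds must be >= 0")
            rates = np.asarray(vt.double_ear_rates, dtype=float)
            if rates.size != len(self.densities):
                problems.append(
                    f"{name}: double-ear profile length {rates.size} != "
                    f"{len(self.densities)} densities"
                )
            elif np.any((rates < 0) | (rates > 100)):
                problems.append(f"{name}: double-ear rates outside [0, 100]")
            elif np.any(np.diff(rates) > 1e-9):
                problems.append(f"{name}: double-ear rates must be "
                                "non-increasing in density")
        if problems:
            raise ValidationError("; ".join(problems))


_HEIGHTS = {"ZD958": 270.0, "XY335": 305.0, "DH661": 260.0,
            "YN103": 255.0, "ZD808": 280.0}


def default_truth(seed: int = 0) -> SyntheticTruth:
    """Truth seeded from the published per-variety fits.

    Hoerl and Weibull parameters, noise standard deviations (the published
    fit SDs) and double-ear profiles all come straight from the reference
    tables; yield scales and morphology defaults are the package's own
    realistic choices (see the methods note).
    """
    varieties = {
        v: VarietyTruth(
            hoerl=ref.hoerl_params(v),
            weibull=ref.weibull_params(v),
            pop_noise_sd=ref.HOERL_FITS[v]["sd"],
            plant_noise_sd=ref.WEIBULL_FITS[v]["sd"],
            double_ear_rates=ref.DOUBLE_EAR_RATES[v],
            max_plant_height=_HEIGHTS[v],
        )
        for v in ref.VARIETIES
    }
    truth = SyntheticTruth(varieties=varieties, seed=seed)
    truth.validate()
    return truth


def _log_frac(x: np.ndarray, densities: Sequence[float]) -> np.ndarray:
    """Position of x in log-density space, 0 at the design minimum,
    1 at the design maximum."""
    lo, hi = math.log(min(densities)), math.log(max(densities))
    return (np.log(x) - lo) / (hi - lo)


def _lerp(rng_pair: tuple[float, float], frac: np.ndarray) -> np.ndarray:
    return rng_pair[0] + (rng_pair[1] - rng_pair[0]) * frac


def simulate_gradient_trial(
    truth: SyntheticTruth,
    densities: Sequence[float] | None = None,
    reps: int = 4,
    years: int = 1,
    *,
    seed: int | None = None,
    plants_per_rep: int = 10,
    scale: str = "relative",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a density-gradient trial.

    Returns ``(trial, traits)``: ``trial`` is a tidy table with columns
    ``variety, year, rep, density, yield, role`` stacking the population
    (per-area) and single-plant responses; ``traits`` holds per-plant ear
    and morphology records.  With ``scale="relative"`` (default, matching
    the normalised data the curve fits consume) yields are relative;
    ``"absolute"`` multiplies by the truth's yield scales (g m⁻² / g).

    The same seed gives byte-identical output.
    """
    truth.validate()
    if scale not in ("relative", "absolute"):
        raise ValidationError(f"scale must be relative|absolute, got {scale!r}")
    if reps < 1 or years < 1:
        raise ValidationError("reps and years must be >= 1")
    dens = np.asarray(densities if densities is not None else truth.densities,
                      dtype=float)
    if np.any(dens <= 0):
        raise ValidationError("densities must be positive")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    morph = truth.morphology
    frac = _log_frac(dens, truth.densities)

    trial_rows: list[pd.DataFrame] = []
    trait_rows: list[pd.DataFrame] = []
    for vname in truth.varieties:
        vt = truth.varieties[vname]
        pop_true = np.asarray(evaluate("hoerl", vt.hoerl, dens))
        plant_true = np.asarray(evaluate("weibull", vt.weibull, dens))
        de_rate = np.interp(dens, truth.densities,
                            np.asarray(vt.double_ear_rates, dtype=float))
        for year in range(1, years + 1):
            year_factor = 1.0 + rng.normal(0.0, truth.year_offset_sd)
            n = dens.size * reps
            d_rep = np.repeat(dens, reps)
            pop = (np.repeat(pop_true, reps)
                   + rng.normal(0.0, vt.pop_noise_sd, n)) * year_factor
            plant = (np.repeat(plant_true, reps)
                     + rng.normal(0.0, vt.plant_noise_sd, n)) * year_factor
            plant = np.maximum(plant, 0.0)  # truncate at zero yield
            pop_y = pop * (truth.reference_yield if scale == "absolute" else 1.0)
            plant_y = plant * (truth.plant_yield_scale
                               if scale == "absolute" else 1.0)
            rep_idx = np.tile(np.arange(1, reps + 1), dens.size)
            trial_rows.append(pd.DataFrame({
                "variety": vname, "year": year, "rep": rep_idx,
                "density": d_rep, "yield": pop_y, "role": "population",
            }))
            trial_rows.append(pd.DataFrame({
                "variety": vname, "year": year, "rep": rep_idx,
                "density": d_rep, "yield": plant_y, "role": "single_plant",
            }))

            # per-plant trait records
            m = dens.size * reps * plants_per_rep
            d_pl = np.repeat(dens, reps * plants_per_rep)
            f_pl = np.repeat(frac, reps * plants_per_rep)
            ear_len = _lerp(morph.ear_length_range, f_pl) + rng.normal(0, 0.8, m)
            bald = np.maximum(
                _lerp(morph.bald_tip_range, f_pl) + rng.normal(0, 0.3, m), 0.0)
            perim = _lerp(morph.ear_perimeter_range, f_pl) + rng.normal(0, 0.5, m)
            tkw = _lerp(morph.tkw_range, f_pl) + rng.normal(0, 12.0, m)
            de_p = np.repeat(de_rate, reps * plants_per_rep) / 100.0
            double = (rng.random(m) < de_p).astype(int)
            p_rel = np.maximum(
                np.repeat(plant_true, reps * plants_per_rep)
                + rng.normal(0, vt.plant_noise_sd, m), 0.0)
            a_rel = np.maximum(
                np.repeat(pop_true, reps * plants_per_rep)
                + rng.normal(0, vt.pop_noise_sd, m), 1e-6)
            plant_yield = p_rel * truth.plant_yield_scale
            area_yield = a_rel * truth.reference_yield
            ears_area = d_pl * (1.0 + de_p) + rng.normal(0, 0.05, m)
            grains_area = area_yield / np.maximum(tkw, 1.0) * 1000.0
            height = vt.max_plant_height * (
                1.0 - morph.height_deficit * np.exp(-morph.height_rate * d_pl)
            ) + rng.normal(0, 4.0, m)
            ear_h = height * _lerp(morph.ear_ratio_range, f_pl)
            stem = morph.stem_base_cm * (1.0 - morph.stem_taper * f_pl) \
                + rng.normal(0, 0.05, m)
            trait_rows.append(pd.DataFrame({
                "variety": vname, "year": year,
                "rep": np.repeat(np.tile(np.arange(1, reps + 1), dens.size),
                                 plants_per_rep),
                "density": d_pl,
                "ear_length": ear_len, "bald_tip_length": bald,
                "ear_perimeter": perim,
                "ears_per_area": ears_area, "grains_per_area": grains_area,
                "thousand_kernel_weight": tkw,
                "plant_yield": plant_yield, "area_yield": area_yield,
                "plant_height": height, "ear_height": ear_h,
                "stem_diameter": stem, "double_ear": double,
            }))

    trial = pd.concat(trial_rows, ignore_index=True)
    traits = pd.concat(trait_rows, ignore_index=True)
    return trial, traits


def simulate_standard_plot(
    truth: SyntheticTruth,
    densities: Sequence[float] = ref.STANDARD_PLOT_DENSITIES,
    reps: int = 3,
    *,
    variety: str | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a conventional fixed-density verification plot.

    Absolute population yields (g m⁻²) at the four standard densities by
    default, ``reps`` replicates each, for one variety (default: the first
    in the truth).  Columns: variety, rep, density, yield, role.
    """
    truth.validate()
    if variety is None:
        variety = next(iter(truth.varieties))
    if variety not in truth.varieties:
        raise ValidationError(f"unknown variety {variety!r}")
    dens = np.asarray(densities, dtype=float)
    if dens.size < 1 or np.any(dens <= 0):
        raise ValidationError("standard-plot densities must be positive")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    vt = truth.varieties[variety]
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rel = np.asarray(evaluate("hoerl", vt.hoerl, dens))
    n = dens.size * reps
    y = (np.repeat(rel, reps) + rng.normal(0, vt.pop_noise_sd, n)) \
        * truth.reference_yield
    return pd.DataFrame({
        "variety": variety,
        "rep": np.tile(np.arange(1, reps + 1), dens.size),
        "density": np.repeat(dens, reps),
        "yield": y,
        "role": "population",
    })


# ---------------------------------------------------------------------------
# correlated trait tables
# ---------------------------------------------------------------------------

TRAIT_CORR_COLUMNS: tuple[str, ...] = (
    "ear_length", "bald_tip_length", "ear_perimeter", "ears_per_area",
    "grains_per_area", "thousand_kernel_weight", "plant_yield", "area_yield",
)

# Target correlation structure following the published ear-trait matrix
# (signs and magnitudes); the per-plant vs per-area yield pair is not
# printed there and is set to a weak negative association.  Projected to
# the nearest positive-semidefinite matrix at import time.

_RAW_TRAIT_CORR = np.array([
    #  EL      BT      EP      EA      GA      TKW     PY      AY
    [ 1.000, -0.446,  0.747,  0.097, -0.027,  0.784,  0.853, -0.072],
    [-0.446,  1.000, -0.723, -0.002, -0.103, -0.615, -0.694,  0.145],
    [ 0.747, -0.723,  1.000, -0.200,  0.019,  0.429,  0.862, -0.212],
    [ 0.097, -0.002, -0.200,  1.000,  0.709, -0.672, -0.921,  0.458],
    [-0.027, -0.103,  0.019,  0.709,  1.000, -0.428, -0.558,  0.833],
    [ 0.784, -0.615,  0.429, -0.672, -0.428,  1.000,  0.683, -0.080],
    [ 0.853, -0.694,  0.862, -0.921, -0.558,  0.683,  1.000, -0.200],
    [-0.072,  0.145, -0.212,  0.458,  0.833, -0.080, -0.200,  1.000],
])

_TRAIT_MEANS = np.array([17.0, 1.5, 14.5, 6.0, 3000.0, 300.0, 160.0, 800.0])
_TRAIT_SDS = np.array([2.0, 0.8, 1.0, 3.5, 800.0, 30.0, 60.0, 120.0])


def _nearest_psd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped projection to the PSD cone, rescaled to unit
    diagonal."""
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    if np.min(w) >= -eps:
        return corr
    w = np.clip(w, eps, None)
    mat = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(mat))
    return mat / np.outer(d, d)


DEFAULT_TRAIT_CORR: np.ndarray = _nearest_psd(_RAW_TRAIT_CORR)


def simulate_trait_table(
    target_corr: np.ndarray | None = None,
    n: int = 65,
    seed: int = 0,
    *,
    columns: Sequence[str] | None = None,
    means: Sequence[float] | None = None,
    sds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Draw an n-record trait table with a target correlation structure.

    A multivariate Gaussian draw (Cholesky of the validated target) shifted
    and scaled to realistic trait values; empirical correlations converge
    to the target as n grows.  The target must be symmetric positive
    semidefinite with unit diagonal.
    """
    corr = np.asarray(DEFAULT_TRAIT_CORR if target_corr is None
                      else target_corr, dtype=float)
    cols = tuple(columns) if columns is not None else (
        TRAIT_CORR_COLUMNS if corr.shape[0] == len(TRAIT_CORR_COLUMNS)
        else tuple(f"trait_{i}" for i in range(corr.shape[0])))
    k = corr.shape[0]
    if corr.shape != (k, k) or len(cols) != k:
        raise ValidationError("target correlation shape/column mismatch")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValidationError("target correlation must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValidationError("target correlation must have unit diagonal")
    w = np.linalg.eigvalsh(corr)
    if np.min(w) < -1e-8:
        raise ValidationError(
            f"target correlation is not positive semidefinite "
            f"(min eigenvalue {np.min(w):.3g})"
        )
    if n < 10:
        raise ValidationError("n must be >= 10")
    mu = np.asarray(means if means is not None else
                    (_TRAIT_MEANS[:k] if k <= len(_TRAIT_MEANS)
                     else np.zeros(k)), dtype=float)
    sig = np.asarray(sds if sds is not None else
                     (_TRAIT_SDS[:k] if k <= len(_TRAIT_SDS)
                      else np.ones(k)), dtype=float)
    rng = np.random.default_rng(seed)
    # eigen-based factor tolerates exact semidefiniteness
    wc = np.clip(w, 0.0, None)
    _, vecs = np.linalg.eigh(corr)  # same ordering as eigvalsh
    factor = vecs @ np.diag(np.sqrt(wc))
    z = rng.standard_normal((n, k)) @ factor.T
    data = mu + sig * z
    return pd.DataFrame(data, columns=list(cols))
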