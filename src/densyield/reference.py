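"""Published reference values for the five-variety maize density study.

Parameter estimates, trial-design constants and summary tables printed in
the original five-year gradient-density field study of Chinese maize
hybrids (Zhengdan 958, Xianyu 335, Denghai 661, Yinong 103, Zhongdan 808).
These serve as generator defaults, documented examples and cross-checks;
the underlying plot-level field records were never deposited, so they are
the only quantitative anchor available.

Densities are plants m⁻², yields g m⁻², spacings cm.
"""

from __future__ import annotations

import math

# --- trial design ----------------------------------------------------------

#: Alternating wide/narrow line spacing, cm (mean 60 cm).
WIDE_NARROW_LINES_CM: tuple[float, float] = (80.0, 40.0)

#: The 13 row spacings (cm) that generate the density gradient.
ROW_SPACINGS_CM: tuple[float, ...] = (
    100.0, 80.0, 60.0, 50.0, 45.0, 40.0, 35.0, 30.0, 25.0, 20.0, 15.0, 12.5, 10.0
)

#: The corresponding printed densities (plants m⁻²).  The 12.5 cm entry was
#: printed at one decimal (13.3); all others at two.
DESIGN_DENSITIES: tuple[float, ...] = (
    1.67, 2.08, 2.78, 3.33, 3.70, 4.17, 4.76, 5.56, 6.67, 8.33, 11.11, 13.3, 16.67
)

#: Fixed densities of the conventional verification ("standard") plots.
STANDARD_PLOT_DENSITIES: tuple[float, ...] = (4.5, 6.0, 7.5, 9.0)

#: Variety labels in a canonical order.
VARIETIES: tuple[str, ...] = ("ZD958", "XY335", "DH661", "YN103", "ZD808")

VARIETY_FULL_NAMES: dict[str, str] = {
    "ZD958": "Zhengdan 958",
    "XY335": "Xianyu 335",
    "DH661": "Denghai 661",
    "YN103": "Yinong 103",
    "ZD808": "Zhongdan 808",
}

# --- per-variety population fits (Hoerl a·bˣ·xᶜ) ---------------------------
# (a, b, c, printed optimal density -c/ln b, fit SD, r)

HOERL_FITS: dict[str, dict[str, float]] = {
    "ZD958": dict(a=0.5903, b=0.9272, c=0.6474, optimum=8.5623, sd=0.0905, r=0.8046),
    "XY335": dict(a=0.4921, b=0.9138, c=0.8044, optimum=8.9289, sd=0.0622, r=0.9398),
    "DH661": dict(a=0.3939, b=0.8937, c=1.0463, optimum=9.3089, sd=0.1419, r=0.8362),
    "YN103": dict(a=0.5525, b=0.9025, c=0.8249, optimum=8.0448, sd=0.0533, r=0.9615),
    "ZD808": dict(a=0.5754, b=0.8813, c=0.7797, optimum=6.1722, sd=0.1095, r=0.7871),
}

#: Pooled population Hoerl equation over all varieties/years.
POOLED_HOERL: tuple[float, float, float] = (0.5139, 0.9142, 0.8004)

# --- per-variety single-plant fits (Weibull m − n·e^(−p·xᵗ)) ---------------

WEIBULL_FITS: dict[str, dict[str, float]] = {
    "XY335": dict(m=1.0589, n=0.8221, p=21.6819, t=-1.8333, sd=0.0162, r=0.9985),
    "DH661": dict(m=1.2681, n=1.0996, p=6.6907, t=-1.2897, sd=0.0163, r=0.9984),
    "ZD958": dict(m=1.0602, n=0.9612, p=15.1895, t=-1.5032, sd=0.0146, r=0.9988),
    "YN103": dict(m=1.1935, n=0.8886, p=25.4885, t=-2.6048, sd=0.0475, r=0.9919),
    "ZD808": dict(m=1.1983, n=0.9747, p=16.5011, t=-2.0138, sd=0.0248, r=0.9985),
}

#: Pooled single-plant Weibull equation.
POOLED_WEIBULL: tuple[float, float, float, float] = (1.0896, 0.9565, 11.4042, -1.4205)

#: Published density-resistance order (descending optimal density).
RESISTANCE_ORDER: tuple[str, ...] = ("DH661", "XY335", "ZD958", "YN103", "ZD808")

# --- printed family rankings -----------------------------------------------
# (family id, fitted params, SD, r) in printed rank order (SD ascending).
# The population ranking pools 20 families; the cosine row's d parameter was
# not legible in the available text and is recorded as None.

POPULATION_FAMILY_RANKING: tuple[tuple, ...] = (
    ("cubic", (0.0866, 0.3795, -0.0366, 0.0011), 0.1617, 0.7094),
    ("rational", (-0.0750, 0.4998, 0.1251, 0.0155), 0.1625, 0.7059),
    ("hoerl", (0.5139, 0.9142, 0.8004), 0.1642, 0.6978),
    ("hoerl_mod", (4.4996, 0.0375, -0.4096), 0.1653, 0.6921),
    ("exp_log", (1.5039, -3.2825, -0.4096), 0.1653, 0.6921),
    ("weibull", (1.2547, 0.8139, 0.0876, 2.1365), 0.1690, 0.6766),
    ("richards", (1.2801, 5.2384, 1.3602, 4.3607), 0.1744, 0.6485),
    ("logistic", (1.2842, 5.6329, 0.9126), 0.1748, 0.6396),
    ("mmf", (0.6216, 290.2861, 1.2823, 4.9440), 0.1754, 0.6389),
    ("gompertz", (1.2858, 1.1270, 0.7789), 0.1754, 0.6338),
    ("exp_assoc2", (2.0265, 0.6320, 0.6188), 0.1711, 0.6299),
    ("quadratic", (0.5760, 0.1534, -0.0073), 0.1728, 0.6266),
    ("cosine", (-7.4411, 8.8201, 0.0401, None), 0.1732, 0.6245),
    ("exp_assoc1", (1.2943, 0.4721), 0.1737, 0.6231),
    ("gaussian", (1.3785, 10.4161, 9.0758), 0.1760, 0.6224),
    ("inv_quadratic", (1.2646, -0.1042, 0.0050), 0.1787, 0.6066),
    ("hyperbolic", (1.4096, -1.2566), 0.1794, 0.6017),
    ("exp_over_x", (1.4296, -1.0818), 0.1824, 0.5835),
    ("root", (1.4296, 0.3390), 0.1824, 0.5835),
    ("saturation", (1.4417, 1.2856), 0.1856, 0.5632),
)

SINGLE_PLANT_FAMILY_RANKING: tuple[tuple, ...] = (
    ("hoerl_mod", (6.3283, 0.1224, -1.0341), 0.0778, 0.9425),
    ("exp_log", (1.8450, -2.1002, -1.0341), 0.0778, 0.9425),
    ("rational", (-55.4524, 68.1952, 13.0568, 11.8894), 0.0779, 0.9426),
    ("weibull", (1.0896, 0.9565, 11.4042, -1.4205), 0.0781, 0.9422),
    ("cubic", (1.3766, -0.1462, 0.0063, -0.0001), 0.0791, 0.9407),
    ("quadratic", (1.3349, -0.1275, 0.0040), 0.0792, 0.9405),
    ("cosine", (2.8548, 2.5391, 0.0584, 2.2226), 0.0794, 0.9403),
    ("inv_power", (0.7559, 0.0544, 1.3890), 0.0795, 0.9399),
    ("inv_quadratic", (0.6892, 0.0922, 0.0046), 0.0801, 0.9390),
    ("recip_power", (0.8241, 0.0596, 0.4824), 0.0802, 0.9389),
)

# --- verification-plot comparison ------------------------------------------
# (density, standard-plot yield, gradient-method yield) for Zhengdan 958;
# printed deviations: 0.96, -1.92, -0.99, -2.52 %.

STANDARD_VS_GRADIENT_YIELDS: tuple[tuple[float, float, float], ...] = (
    (4.5, 855.54, 863.74),
    (6.7, 883.19, 866.26),
    (9.0, 1024.18, 1014.01),
    (11.2, 910.99, 888.03),
)

#: Reported squared correlation of simulated vs measured standard-plot yield.
VERIFICATION_ACCURACY: float = 0.8516

# --- double-ear occurrence (% of plants with two ears), by design density --
# Rates decline with density; single-ear varieties are all-zero rows.

DOUBLE_EAR_RATES: dict[str, tuple[float, ...]] = {
    "ZD958": (40.0, 35.0, 35.0, 7.5, 5.0, 5.0, 5.0, 2.5, 2.5, 0, 0, 0, 0),
    "XY335": (55.0, 22.5, 5.1, 2.5, 2.5, 0, 0, 0, 0, 0, 0, 0, 0),
    "DH661": (0,) * 13,
    "YN103": (42.5, 25.0, 22.5, 15.0, 5.0, 2.5, 2.5, 0, 0, 0, 0, 0, 0),
    "ZD808": (0,) * 13,
}


def printed_optimal_densities() -> dict[str, float]:
    """The published per-variety optimal densities (−c/ln b column)."""
    return {v: HOERL_FITS[v]["optimum"] for v in VARIETIES}


def hoerl_params(variety: str) -> tuple[float, float, float]:
    f = HOERL_FITS[variety]
    return (f["a"], f["b"], f["c"])


def weibull_params(variety: str) -> tuple[float, float, float, float]:
    f = WEIBULL_FITS[variety]
    return (f["m"], f["n"], f["p"], f["t"])


def _self_check() -> None:
    # sanity: printed optima agree with -c/ln b at the printed rounding
    for v, f in HOERL_FITS.items():
        assert abs(-f["c"] / math.log(f["b"]) / f["optimum"] - 1) < 1e-3, v


_self_check()
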