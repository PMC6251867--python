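"""Resistance analytics: normalisation, optima, rankings, verification."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import densyield as dy
from densyield import reference as ref
from densyield.errors import (
    DensityDomainError,
    InsufficientDataError,
    NormalizationError,
    ParameterDomainError,
)


class TestNormalize:
    def test_proportional_scaling_to_minimum_density(self):
        tab = pd.DataFrame({"density": [3.33, 6.67, 8.33],
                            "yield": [600.0, 900.0, 1000.0]})
        out = dy.normalize(tab)
        np.testing.assert_allclose(out["yield"], [1.0, 1.5, 1000 / 600])

    def test_single_record(self):
        out = dy.normalize(pd.DataFrame({"density": [5.0], "yield": [720.0]}))
        assert out["yield"].iloc[0] == 1.0

    def test_fixed_reference_missing_names_group(self):
        tab = pd.DataFrame({"variety": ["A"] * 3,
                            "density": [1.67, 6.67, 8.33],
                            "yield": [600.0, 900.0, 1000.0]})
        with pytest.raises(NormalizationError, match="A"):
            dy.normalize(tab, reference="fixed:3.33")

    def test_groups_normalised_independently(self):
        tab = pd.DataFrame({
            "variety": ["A", "A", "B", "B"],
            "density": [2.0, 4.0, 2.0, 4.0],
            "yield": [500.0, 750.0, 1000.0, 1200.0],
        })
        out = dy.normalize(tab)
        a = out[out.variety == "A"]["yield"].to_numpy()
        b = out[out.variety == "B"]["yield"].to_numpy()
        np.testing.assert_allclose(a, [1.0, 1.5])
        np.testing.assert_allclose(b, [1.0, 1.2])

    def test_reference_uses_group_mean_over_replicates(self):
        tab = pd.DataFrame({"density": [2.0, 2.0, 5.0],
                            "yield": [90.0, 110.0, 200.0]})
        out = dy.normalize(tab)
        np.testing.assert_allclose(out["yield"], [0.9, 1.1, 2.0])


class TestOptimalDensity:
    @pytest.mark.parametrize("variety", ref.VARIETIES)
    def test_matches_published_optima(self, variety):
        x_star = dy.optimal_density(ref.hoerl_params(variety))
        assert x_star == pytest.approx(ref.HOERL_FITS[variety]["optimum"],
                                       rel=1e-3)

    def test_closed_form_agrees_with_grid_argmax(self):
        x_star = dy.optimal_density(ref.POOLED_HOERL)
        assert abs(x_star - dy.grid_argmax(ref.POOLED_HOERL)) < 1e-3

    @pytest.mark.parametrize("bad", [(0.5, 1.1, 0.8), (0.5, 0.9, -0.2),
                                     (-1.0, 0.9, 0.8)])
    def test_inadmissible_parameters_rejected(self, bad):
        with pytest.raises(ParameterDomainError):
            dy.optimal_density(bad)


class TestChangeRate:
    def test_zero_at_optimum(self):
        p = ref.hoerl_params("XY335")
        assert dy.change_rate(p, dy.optimal_density(p)) == pytest.approx(
            0.0, abs=1e-12)

    def test_sign_straddles_published_optimum(self):
        p = ref.hoerl_params("DH661")  # published optimum 9.3089
        assert dy.change_rate(p, 2.0) > 0
        assert dy.change_rate(p, 12.0) < 0

    def test_matches_finite_difference(self):
        p = ref.hoerl_params("ZD958")
        rng = np.random.default_rng(21)
        for x in rng.uniform(0.5, 16.0, 10):
            h = 1e-6 * x
            fd = (dy.evaluate("hoerl", p, x + h)
                  - dy.evaluate("hoerl", p, x - h)) / (2 * h)
            assert dy.change_rate(p, x) == pytest.approx(fd, rel=1e-6,
                                                         abs=1e-9)

    def test_integrates_to_yield_difference(self):
        p = ref.hoerl_params("YN103")
        lo, hi = 2.0, 9.5
        integral, _ = quad(lambda x: dy.change_rate(p, x), lo, hi,
                           epsabs=1e-10)
        expected = dy.evaluate("hoerl", p, hi) - dy.evaluate("hoerl", p, lo)
        assert integral == pytest.approx(expected, abs=1e-6)


class TestResistanceRanking:
    def test_published_order(self):
        reports = dy.resistance_ranking(
            {v: ref.hoerl_params(v) for v in ref.VARIETIES})
        assert tuple(r.label for r in reports) == ref.RESISTANCE_ORDER
        assert [r.rank for r in reports] == [1, 2, 3, 4, 5]

    def test_input_order_invariance(self):
        fwd = dy.resistance_ranking(
            [(v, ref.hoerl_params(v)) for v in ref.VARIETIES])
        rev = dy.resistance_ranking(
            [(v, ref.hoerl_params(v)) for v in reversed(ref.VARIETIES)])
        assert [r.label for r in fwd] == [r.label for r in rev]

    def test_single_variety(self):
        reports = dy.resistance_ranking({"ZD958": ref.hoerl_params("ZD958")})
        assert reports[0].rank == 1

    def test_identical_params_tie_broken_by_label(self):
        p = ref.hoerl_params("ZD958")
        reports = dy.resistance_ranking([("beta", p), ("alpha", p)])
        assert [r.label for r in reports] == ["alpha", "beta"]

    def test_non_hoerl_fit_raises(self):
        bad = dy.FitResult("quadratic", (1.0, 0.1, -0.01), 0.1, 0.9, 13,
                           True, label="X")
        with pytest.raises(TypeError):
            dy.resistance_ranking([bad])

    def test_descending_optimal_density(self):
        reports = dy.resistance_ranking(
            {v: ref.hoerl_params(v) for v in ref.VARIETIES})
        opts = [r.optimal_density for r in reports]
        assert opts == sorted(opts, reverse=True)


class TestSinglePlantDecline:
    def test_constant_curve_has_zero_decline(self):
        assert dy.single_plant_decline((1.0, 0.0, 5.0, -1.5)) == 0.0

    def test_published_zhengdan_decline(self):
        # hand evaluation of the Weibull endpoints over the design range
        rate = dy.single_plant_decline(ref.weibull_params("ZD958"))
        assert rate == pytest.approx(0.05131, abs=1e-4)

    def test_equals_mean_negative_derivative_by_quadrature(self):
        p = ref.weibull_params("DH661")
        lo, hi = 1.67, 16.67
        integral, _ = quad(
            lambda x: -dy.derivative("weibull", p, x), lo, hi, epsabs=1e-11)
        assert dy.single_plant_decline(p) == pytest.approx(
            integral / (hi - lo), abs=1e-8)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(DensityDomainError):
            dy.single_plant_decline(ref.weibull_params("ZD958"), (5.0, 5.0))


class TestDesignArithmetic:
    def test_extreme_row_spacings(self):
        assert dy.spacing_to_density(100.0) == pytest.approx(1.6667, abs=5e-3)
        assert dy.spacing_to_density(10.0) == pytest.approx(16.667, abs=5e-2)

    def test_unit_square(self):
        assert dy.spacing_to_density(100.0, (100.0, 100.0)) == pytest.approx(1.0)

    def test_full_design_density_list(self):
        for row, printed in zip(ref.ROW_SPACINGS_CM, ref.DESIGN_DENSITIES):
            got = dy.spacing_to_density(row)
            decimals = 1 if printed == 13.3 else 2
            assert round(got, decimals) == printed

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(DensityDomainError):
            dy.spacing_to_density(0.0)
        with pytest.raises(DensityDomainError):
            dy.spacing_to_density(50.0, (80.0, -40.0))


class TestPercentDeviation:
    @pytest.mark.parametrize("standard, gradient, expected", [
        (855.54, 863.74, 0.96),
        (883.19, 866.26, -1.92),
        (1024.18, 1014.01, -0.99),
        (910.99, 888.03, -2.52),
    ])
    def test_published_pairs(self, standard, gradient, expected):
        assert dy.percent_deviation(standard, gradient) == expected

    def test_identical_yields(self):
        assert dy.percent_deviation(712.3, 712.3) == 0.0

    def test_zero_standard_rejected(self):
        with pytest.raises(DensityDomainError):
            dy.percent_deviation(0.0, 500.0)

    def test_asymmetry_identity(self):
        a, b = 855.54, 863.74
        lhs = dy.percent_deviation(a, b)
        rhs = -dy.percent_deviation(b, a) * (b / a)
        assert lhs == pytest.approx(rhs, abs=0.01)


class TestVerification:
    def _standard_frame(self, params, densities=(4.5, 6.0, 7.5, 9.0),
                        scale=800.0):
        rel = np.asarray(dy.evaluate("hoerl", params, np.asarray(densities)))
        rel = rel / rel[0] * scale
        return pd.DataFrame({"density": densities, "yield": rel})

    def test_perfect_agreement(self):
        p = ref.hoerl_params("ZD958")
        std = self._standard_frame(p)
        v = dy.verify_against_standard(p, std)
        assert v.slope == pytest.approx(1.0)
        assert v.intercept == pytest.approx(0.0, abs=1e-9)
        assert v.accuracy == pytest.approx(1.0)
        assert all(dev == 0.0 for _, dev in v.deviations)

    def test_noisy_standard_plot_within_envelope(self):
        """With the printed noise level, accuracy stays above the 200-rep
        Monte-Carlo floor and mean |deviation| under 10% (the published
        average fluctuation was 4.45%)."""
        truth = dy.default_truth()
        std = dy.simulate_standard_plot(truth, variety="ZD958", seed=42)
        v = dy.verify_against_standard(ref.hoerl_params("ZD958"), std)
        assert v.accuracy > 0.05
        assert v.mean_abs_deviation < 10.0

    def test_uncorrelated_measurements_give_near_zero_accuracy(self):
        p = ref.hoerl_params("ZD958")
        rng = np.random.default_rng(13)
        std = pd.DataFrame({
            "density": [4.5, 6.0, 7.5, 9.0],
            "yield": 800.0 + rng.normal(0, 1.0, 4),  # flat: no signal
        })
        v = dy.verify_against_standard(p, std)
        assert v.accuracy < 0.5

    def test_too_few_densities_rejected(self):
        p = ref.hoerl_params("ZD958")
        std = pd.DataFrame({"density": [4.5, 6.0], "yield": [800.0, 900.0]})
        with pytest.raises(InsufficientDataError):
            dy.verify_against_standard(p, std)
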