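"""Curve-family catalog: evaluation, derivatives, limits, completeness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import densyield as dy
from densyield import reference as ref
from densyield.errors import (
    CatalogError,
    DensityDomainError,
    ParameterDomainError,
)

from conftest import printed_population_rows, printed_single_plant_rows


class TestEvaluate:
    @pytest.mark.parametrize("model_id, params, x, expected, tol", [
        # pooled population curve, hand evaluation of a*b^x*x^c
        ("hoerl", ref.POOLED_HOERL, 3.33, 0.998413, 1e-5),
        # x^c == 1 at x == 1, so y = a*b exactly
        ("hoerl", ref.POOLED_HOERL, 1.0, 0.5139 * 0.9142, 1e-12),
        # hand evaluation of m - n*exp(-p*x^t) for Zhengdan 958
        ("weibull", (1.0602, 0.9612, 15.1895, -1.5032), 3.33, 0.980510, 1e-5),
    ])
    def test_known_values(self, model_id, params, x, expected, tol):
        assert dy.evaluate(model_id, params, x) == pytest.approx(expected, abs=tol)

    def test_vectorised_matches_scalar(self, design_densities, pooled_hoerl):
        vec = dy.evaluate("hoerl", pooled_hoerl, design_densities)
        scal = [dy.evaluate("hoerl", pooled_hoerl, x) for x in design_densities]
        np.testing.assert_allclose(vec, scal, rtol=1e-14)

    def test_unknown_family(self):
        with pytest.raises(CatalogError):
            dy.evaluate("parabola_deluxe", (1.0,), 2.0)

    @pytest.mark.parametrize("bad", [
        (-0.5, 0.9, 0.8),   # a <= 0
        (0.5, 1.2, 0.8),    # b outside (0, 1)
        (0.5, 0.9, -0.1),   # c <= 0
    ])
    def test_hoerl_constraint_violation(self, bad):
        with pytest.raises(ParameterDomainError):
            dy.evaluate("hoerl", bad, 2.0)

    def test_weibull_rate_must_be_positive(self):
        with pytest.raises(ParameterDomainError):
            dy.evaluate("weibull", (1.0, 0.9, -1.0, -1.5), 2.0)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(DensityDomainError):
            dy.evaluate("hoerl", ref.POOLED_HOERL, 0.0)
        with pytest.raises(DensityDomainError):
            dy.evaluate("hoerl", ref.POOLED_HOERL, -3.0)


class TestDerivative:
    def test_hoerl_vanishes_at_optimum(self):
        p = ref.hoerl_params("ZD958")
        x_star = dy.optimal_density(p)
        assert dy.derivative("hoerl", p, x_star) == pytest.approx(0.0, abs=1e-12)

    def test_hoerl_at_unit_density(self):
        # a*b*(ln b + c) by hand for Zhengdan 958
        a, b, c = ref.hoerl_params("ZD958")
        expected = a * b * (math.log(b) + c)
        assert dy.derivative("hoerl", (a, b, c), 1.0) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(0.3130, abs=5e-4)

    def test_weibull_negative_on_design_range(self):
        p = ref.weibull_params("ZD958")
        xs = np.linspace(1.67, 16.67, 50)
        assert np.all(dy.derivative("weibull", p, xs) < 0)

    @pytest.mark.parametrize("model_id, params",
                             [(m, p) for m, p, _, _ in printed_population_rows()]
                             + [(m, p) for m, p, _, _ in printed_single_plant_rows()])
    def test_matches_independent_finite_difference(self, model_id, params):
        """Closed-form (or fallback) derivative agrees with an independent
        central difference at 20 random admissible densities."""
        rng = np.random.default_rng(42)
        xs = rng.uniform(0.5, 20.0, 20)
        d = np.asarray(dy.derivative(model_id, params, xs))
        h = 1e-5 * xs
        fd = (np.asarray(dy.evaluate(model_id, params, xs + h))
              - np.asarray(dy.evaluate(model_id, params, xs - h))) / (2 * h)
        tol = 1e-6 if dy.get_model(model_id).has_closed_derivative else 1e-4
        ref_scale = max(float(np.max(np.abs(fd))), 1e-6)
        np.testing.assert_allclose(d, fd, rtol=tol, atol=tol * ref_scale)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(b=st.floats(0.55, 0.98), c=st.floats(0.1, 2.5))
    def test_hoerl_unimodal_shape(self, b, c):
        """Admissible Hoerl curves rise strictly before −c/ln b and fall
        strictly after."""
        params = (0.7, b, c)
        x_star = -c / math.log(b)
        below = np.linspace(0.01 * x_star, 0.99 * x_star, 25)
        above = np.linspace(1.01 * x_star, 3.0 * x_star, 25)
        assert np.all(np.asarray(dy.derivative("hoerl", params, below)) > 0)
        assert np.all(np.asarray(dy.derivative("hoerl", params, above)) < 0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(m=st.floats(0.9, 1.3), n=st.floats(0.5, 1.1),
           p=st.floats(2.0, 30.0), t=st.floats(-3.0, -0.8))
    def test_weibull_decline_is_monotone(self, m, n, p, t):
        xs = np.geomspace(0.05, 100.0, 60)
        d = np.asarray(dy.derivative("weibull", (m, n, p, t), xs))
        assert np.all(d <= 1e-12)


class TestLimits:
    @pytest.mark.parametrize("model_id, params, expected", [
        ("hoerl", ref.POOLED_HOERL, (0.0, 0.0)),
        ("cubic", (0.0866, 0.3795, -0.0366, 0.0011), (0.0866, math.inf)),
        ("rational", (-0.0750, 0.4998, 0.1251, 0.0155), (-0.0750, 0.0)),
    ])
    def test_symbolic_rules(self, model_id, params, expected):
        lo, hi = dy.limit_behavior(model_id, params)
        assert lo == pytest.approx(expected[0])
        if math.isinf(expected[1]):
            assert hi == expected[1]
        else:
            assert hi == pytest.approx(expected[1])

    @pytest.mark.parametrize("model_id, params",
                             [(m, p) for m, p, _, _ in printed_population_rows()]
                             + [(m, p) for m, p, _, _ in printed_single_plant_rows()])
    def test_symbolic_agrees_with_numeric_probe(self, model_id, params):
        """Overflow-safe probes at x=1e-8 and x=1e8 must not contradict the
        symbolic limit (slowly-converging tails get a loose band)."""
        sym = dy.limit_behavior(model_id, params)
        probe = dy.numeric_limit_probe(model_id, params)
        for s, pr in zip(sym, probe):
            if math.isnan(s):
                continue  # oscillatory: no limit to check
            if math.isinf(s):
                assert abs(pr) > 1e5 and math.copysign(1, pr) == math.copysign(1, s)
            elif s == 0.0:
                assert abs(pr) < 0.05
            else:
                assert pr == pytest.approx(s, rel=0.05, abs=0.05)


class TestCatalogContents:
    def test_family_counts(self):
        assert len(dy.CATALOG) == 22
        assert len(dy.POPULATION_FAMILIES) == 20
        assert len(dy.SINGLE_PLANT_FAMILIES) == 10

    def test_printed_rows_match_parameter_counts(self):
        for mid, params, _, _ in list(printed_population_rows(
                include_partial=True)) + list(printed_single_plant_rows()):
            assert dy.get_model(mid).n_params == len(params)

    def test_every_ranked_family_registered_once(self):
        pop = [m for m, *_ in ref.POPULATION_FAMILY_RANKING]
        single = [m for m, *_ in ref.SINGLE_PLANT_FAMILY_RANKING]
        assert len(pop) == len(set(pop)) and len(single) == len(set(single))
        assert set(pop) == set(dy.POPULATION_FAMILIES)
        assert set(single) == set(dy.SINGLE_PLANT_FAMILIES)

    def test_export_catalog_listing(self):
        df = dy.export_catalog()
        assert len(df) == len(dy.CATALOG)
        assert df["id"].is_unique
        assert set(df.columns) >= {"id", "formula", "params", "constraints",
                                   "roles"}
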