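"""Least-squares fitting, goodness statistics, catalog ranking."""

import math

import numpy as np
import pandas as pd
import pytest

import densyield as dy
from densyield import reference as ref
from densyield.errors import (
    DegreesOfFreedomError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)


class TestGoodness:
    def test_perfect_fit(self):
        obs = [1.0, 2.0, 3.0, 4.0]
        sd, r, stars = dy.goodness(obs, obs, k=2)
        assert sd == 0.0
        assert r == pytest.approx(1.0)
        assert stars == "**"

    def test_definitional_oracle(self):
        """Both statistics match an independent hand computation of the
        defining formulas (SSE = 0.10, covariance ratio r = 0.99520)."""
        obs = [1.0, 2.0, 3.0, 4.0, 5.0]
        fit = [1.1, 1.9, 3.2, 3.8, 5.0]
        sd, r, stars = dy.goodness(obs, fit, k=2)
        assert sd == pytest.approx(math.sqrt(0.10 / 3), rel=1e-12)
        assert r == pytest.approx(9.7 / math.sqrt(10 * 9.5), rel=1e-12)
        assert stars == "**"

    def test_large_sample_correlation_is_double_starred(self):
        # the smallest double-starred magnitude in the published ear-trait
        # matrix: |r| = 0.4464 at n = 65
        assert dy.significance_stars(0.4464, 65) == "**"
        assert dy.significance_stars(-0.4464, 65) == "**"

    def test_modest_correlation_small_n_unstarred(self):
        assert dy.significance_stars(0.30, 10) == ""

    def test_degrees_of_freedom_error(self):
        with pytest.raises(DegreesOfFreedomError):
            dy.goodness([1.0, 2.0], [1.0, 2.0], k=2)

    def test_zero_variance_error(self):
        with pytest.raises(UndefinedCorrelationError):
            dy.goodness([1.0, 1.0, 1.0, 1.0], [1.0, 1.1, 0.9, 1.0], k=1)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        obs = rng.normal(size=12)
        fit = obs + rng.normal(0, 0.1, 12)
        perm = rng.permutation(12)
        assert dy.goodness(obs, fit, 2)[:2] == pytest.approx(
            dy.goodness(obs[perm], fit[perm], 2)[:2])

    def test_joint_affine_invariance_of_r(self):
        rng = np.random.default_rng(4)
        obs = rng.normal(size=15)
        fit = obs + rng.normal(0, 0.3, 15)
        _, r1, _ = dy.goodness(obs, fit, 2)
        _, r2, _ = dy.goodness(5.0 * obs - 2.0, 5.0 * fit - 2.0, 2)
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestFit:
    def test_noise_free_hoerl_recovery(self, noise_free_hoerl_table,
                                       pooled_hoerl):
        res = dy.fit("hoerl", noise_free_hoerl_table)
        assert res.converged
        np.testing.assert_allclose(res.params, pooled_hoerl, rtol=1e-6)
        assert res.sd == pytest.approx(0.0, abs=1e-9)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_weibull_recovery(self, design_densities):
        truth = ref.weibull_params("XY335")
        y = dy.evaluate("weibull", truth, design_densities)
        table = pd.DataFrame({"density": design_densities, "yield": y})
        res = dy.fit("weibull", table)
        np.testing.assert_allclose(res.params, truth, rtol=1e-5)

    def test_noisy_hoerl_within_monte_carlo_envelope(self, design_densities,
                                                     pooled_hoerl):
        """At noise sd 0.16 (4 reps/density) the recovered parameters stay
        within 3 Monte-Carlo standard errors of truth and the fit SD within
        the simulation envelope [0.10, 0.22].  MC SEs (a: 0.054, b: 0.015,
        c: 0.115) were established by a 500-replicate brute-force oracle."""
        rng = np.random.default_rng(2024)
        x = np.repeat(design_densities, 4)
        y = np.asarray(dy.evaluate("hoerl", pooled_hoerl, x)) \
            + rng.normal(0, 0.16, x.size)
        res = dy.fit("hoerl", pd.DataFrame({"density": x, "yield": y}),
                     dy.FitOptions(seed=2024))
        mc_se = (0.054, 0.015, 0.115)
        for est, true, se in zip(res.params, pooled_hoerl, mc_se):
            assert abs(est - true) < 3 * se
        assert 0.10 < res.sd < 0.22

    def test_same_seed_is_bit_reproducible(self, design_densities,
                                           pooled_hoerl):
        rng = np.random.default_rng(7)
        x = np.repeat(design_densities, 2)
        y = np.asarray(dy.evaluate("hoerl", pooled_hoerl, x)) \
            + rng.normal(0, 0.08, x.size)
        tab = pd.DataFrame({"density": x, "yield": y})
        opts = dy.FitOptions(n_starts=12, seed=99)
        r1 = dy.fit("hoerl", tab, opts)
        r2 = dy.fit("hoerl", tab, opts)
        assert r1.params == r2.params
        assert r1.sd == r2.sd

    def test_insufficient_distinct_densities(self):
        tab = pd.DataFrame({"density": [2.0, 4.0, 6.0, 8.0],
                            "yield": [0.5, 0.9, 1.0, 0.9]})
        with pytest.raises(InsufficientDataError):
            dy.fit("hoerl", tab)  # 3-param family needs >= 5

    def test_mixed_roles_rejected(self, design_densities, pooled_hoerl):
        y = dy.evaluate("hoerl", pooled_hoerl, design_densities)
        tab = pd.DataFrame({"density": design_densities, "yield": y,
                            "role": ["population"] * 7 + ["single_plant"] * 6})
        with pytest.raises(ValidationError):
            dy.fit("hoerl", tab)

    def test_use_means_collapses_replicates(self, design_densities,
                                            pooled_hoerl):
        rng = np.random.default_rng(11)
        x = np.repeat(design_densities, 3)
        y = np.asarray(dy.evaluate("hoerl", pooled_hoerl, x)) \
            + rng.normal(0, 0.05, x.size)
        tab = pd.DataFrame({"density": x, "yield": y})
        res = dy.fit("hoerl", tab, dy.FitOptions(use_means=True))
        assert res.n == len(design_densities)


class TestFitCatalog:
    def test_noise_free_hoerl_ranked_first(self, noise_free_hoerl_table):
        ranked = dy.fit_catalog(
            noise_free_hoerl_table, ("quadratic", "hoerl", "logistic"),
            dy.FitOptions(n_starts=8))
        assert ranked[0].model_id == "hoerl"
        assert ranked[0].sd == pytest.approx(0.0, abs=1e-9)

    def test_ranking_orders_by_sd_then_r_then_parsimony(self):
        mk = lambda mid, k, sd, r: dy.FitResult(mid, (0.0,) * k, sd, r, 13, True)
        fits = [mk("cubic", 4, 0.20, 0.9), mk("quadratic", 3, 0.10, 0.8),
                mk("hoerl", 3, 0.10, 0.9),
                dy.FitResult("mmf", (), math.inf, math.nan, 13, False)]
        ranked = dy.rank_fits(fits)
        assert [f.model_id for f in ranked] == [
            "hoerl", "quadratic", "cubic", "mmf"]

    def test_per_family_failure_does_not_abort(self, noise_free_hoerl_table):
        ranked = dy.fit_catalog(noise_free_hoerl_table,
                                ("hoerl", "no_such_family"),
                                dy.FitOptions(n_starts=4))
        assert len(ranked) == 2
        flagged = [f for f in ranked if not f.converged]
        assert len(flagged) == 1 and flagged[0].model_id == "no_such_family"

    def test_synthetic_population_ranking_places_hoerl_high(self):
        """On pooled synthetic gradient data the Hoerl family lands in the
        top 10 of the full population ranking (qualitative reproduction of
        the published placement)."""
        truth = dy.default_truth(seed=5)
        trial, _ = dy.simulate_gradient_trial(truth, seed=5, years=2,
                                              plants_per_rep=1)
        pooled = dy.normalize(trial[trial.role == "population"])
        ranked = dy.fit_catalog(pooled, dy.POPULATION_FAMILIES,
                                dy.FitOptions(n_starts=8, seed=5))
        top10 = [f.model_id for f in ranked[:10]]
        assert "hoerl" in top10

    def test_synthetic_single_plant_ranking_places_weibull_high(self):
        truth = dy.default_truth(seed=6)
        trial, _ = dy.simulate_gradient_trial(truth, seed=6, years=2,
                                              plants_per_rep=1)
        pooled = dy.normalize(trial[trial.role == "single_plant"])
        ranked = dy.fit_catalog(pooled, dy.SINGLE_PLANT_FAMILIES,
                                dy.FitOptions(n_starts=8, seed=6))
        top10 = [f.model_id for f in ranked[:10]]
        assert "weibull" in top10

    def test_parameter_recovery_median_error(self, design_densities):
        """Median relative error of each Hoerl parameter stays below 10%
        over 50 seeded replicates at noise sd 0.05 (13 densities x 4 reps)."""
        truth = ref.POOLED_HOERL
        x = np.repeat(design_densities, 4)
        clean = np.asarray(dy.evaluate("hoerl", truth, x))
        errs = []
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            tab = pd.DataFrame({"density": x,
                                "yield": clean + rng.normal(0, 0.05, x.size)})
            res = dy.fit("hoerl", tab, dy.FitOptions(n_starts=6, seed=s))
            errs.append([abs(e / t - 1.0) for e, t in zip(res.params, truth)])
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.10)


def test_fit_report_frame(noise_free_hoerl_table):
    ranked = dy.fit_catalog(noise_free_hoerl_table, ("hoerl", "quadratic"),
                            dy.FitOptions(n_starts=6))
    rep = dy.fit_report(ranked)
    assert list(rep["rank"]) == [1, 2]
    assert rep.loc[0, "model"] == "hoerl"
    assert {"SD", "r", "signif", "formula"} <= set(rep.columns)
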