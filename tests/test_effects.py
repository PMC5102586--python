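"""Pooling arithmetic, CI widening, significance flags, effect translation
and the spatial residual diagnostic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from propstrat.effects import (GroupEffect, ModelSpec, PooledEffect,
                               StratifiedEffectEstimator, adjust_fcr,
                               by_widening_factor, fit_direct_model,
                               fit_group_models, flag_significance, harmonic,
                               pool_estimates, reference_baseline,
                               residual_semivariogram, translate_effect)
from propstrat.propensity import Stratification, fit_propensity, stratify
from propstrat.synthetic import GeneratorConfig, generate_sites


def _ge(group, coef, se, n):
    return GroupEffect(group=group, coef=coef, se=se, n=n)


class TestPooling:
    def test_single_group_identity(self):
        pooled = pool_estimates([_ge(0, 1.5, 0.4, 50)])
        assert pooled.estimate == pytest.approx(1.5)
        assert pooled.ci_halfwidth == pytest.approx(1.96 * 0.4, rel=1e-4)

    def test_equal_groups_equal_se_closed_form(self):
        groups = [_ge(g, float(g), 1.0, 20) for g in range(5)]
        pooled = pool_estimates(groups)
        assert pooled.ci_halfwidth == pytest.approx(1.96 / np.sqrt(5), rel=1e-4)

    def test_hand_computed_three_group_example(self):
        groups = [_ge(0, 1.0, 0.3, 10), _ge(1, 2.0, 0.2, 20), _ge(2, 3.0, 0.1, 30)]
        pooled = pool_estimates(groups)
        assert pooled.estimate == pytest.approx(2.3333, abs=1e-4)
        assert pooled.ci_halfwidth == pytest.approx(0.1905, abs=1e-4)

    def test_estimate_is_convex_combination(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            coefs = rng.normal(size=4)
            groups = [_ge(i, c, rng.uniform(0.1, 1), int(rng.integers(10, 50)))
                      for i, c in enumerate(coefs)]
            pooled = pool_estimates(groups)
            assert coefs.min() - 1e-12 <= pooled.estimate <= coefs.max() + 1e-12

    def test_empty_group_list_rejected(self):
        with pytest.raises(ValueError):
            pool_estimates([])

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            _ge(0, 1.0, 0.0, 10)


class TestFcrAdjustment:
    def test_m1_leaves_interval_unchanged(self):
        p = pool_estimates([_ge(0, 0.5, 0.1, 30)])
        adj, = adjust_fcr([p], m=1)
        assert adj.adj_halfwidth == pytest.approx(p.ci_halfwidth, rel=1e-6)

    def test_m20_widening_matches_harmonic_quantile(self):
        assert harmonic(20) == pytest.approx(3.5977, abs=1e-4)
        alpha_adj = 0.05 / harmonic(20)
        assert alpha_adj == pytest.approx(0.013898, abs=1e-5)
        z = stats.norm.ppf(1 - alpha_adj / 2)
        assert z == pytest.approx(2.460, abs=1e-3)
        assert by_widening_factor(20) == pytest.approx(1.255, abs=2e-3)

    @pytest.mark.parametrize("m", [2, 5, 10, 40])
    def test_any_m_above_one_widens(self, m):
        assert by_widening_factor(m) > 1.0
        p = pool_estimates([_ge(0, 0.5, 0.1, 30)])
        adj, = adjust_fcr([p], m=m)
        assert adj.adj_halfwidth > adj.ci_halfwidth

    def test_fcr_variant_and_bad_q(self):
        p = pool_estimates([_ge(0, 2.0, 0.1, 30)])
        adj, = adjust_fcr([p], m=4, method="fcr")
        assert adj.adj_halfwidth > 0
        with pytest.raises(ValueError):
            adjust_fcr([p], m=4, q=1.5)


class TestSignificance:
    def test_interval_excluding_zero(self):
        p = PooledEffect("r", "gaussian", 0.5, se=1.0, k=1, n=10,
                         ci_halfwidth=0.4, adj_halfwidth=0.4)
        assert flag_significance(p)

    def test_interval_spanning_zero(self):
        p = PooledEffect("r", "gaussian", 0.5, se=1.0, k=1, n=10,
                         ci_halfwidth=0.6, adj_halfwidth=0.6)
        assert not flag_significance(p)

    def test_odds_ratio_spanning_one(self):
        # estimate chosen so the OR interval is (0.99, 1.20)
        est = (np.log(0.99) + np.log(1.20)) / 2
        hw = (np.log(1.20) - np.log(0.99)) / 2
        p = PooledEffect("r", "binomial", est, se=1.0, k=1, n=10,
                         ci_halfwidth=hw, adj_halfwidth=hw)
        lo, hi = p.odds_ratio_ci
        assert (lo, hi) == (pytest.approx(0.99), pytest.approx(1.20))
        assert not flag_significance(p)


class TestGroupModels:
    def test_single_gaussian_group_reduces_to_ols_slope(self):
        rng = np.random.default_rng(4)
        n = 120
        treat = rng.uniform(0, 100, n)
        # covariates orthogonalized against the treatment
        cov = rng.normal(size=n)
        cov -= np.polyval(np.polyfit(treat, cov, 1), treat)
        y = 0.03 * treat + 0.5 * cov + rng.normal(0, 1, n)
        sites = pd.DataFrame({"t": treat, "c": cov, "y": y})
        strat = Stratification(k=1, labels=pd.Series(np.zeros(n, int)),
                               boundaries=np.array([]))
        spec = ModelSpec(response="y", family="gaussian", treatment="t",
                         continuous=["c"], categorical=[])
        eff, = fit_group_models(sites, strat, spec)
        slope = np.polyfit(treat, y, 1)[0]
        assert eff.coef == pytest.approx(slope, abs=1e-10)

    def test_null_effects_centred_on_zero(self):
        effects = {"silt_deposits": 0.0}
        coefs = []
        for seed in range(40):
            cfg = GeneratorConfig(n_sites=600, seed=seed, confounding_strength=0.5,
                                  true_effects=effects)
            sites, _ = generate_sites(cfg)
            fit = fit_propensity(sites, "arable_catch")
            strat = stratify(fit, 5)
            spec = ModelSpec(response="silt_deposits", family="binomial")
            pooled = pool_estimates(fit_group_models(sites, strat, spec))
            coefs.append(pooled.estimate)
        mean_se = np.std(coefs) / np.sqrt(len(coefs))
        assert abs(np.mean(coefs)) < 3 * mean_se + 1e-4

    def test_separated_group_excluded_with_warning(self, default_sites):
        sites, _, _ = default_sites
        sites = sites.head(500).copy()
        fit = fit_propensity(sites, "arable_catch")
        strat = stratify(fit, 5)
        labels = strat.labels.to_numpy()
        sites.loc[labels == 2, "silt_deposits"] = 1  # constant in group 2
        spec = ModelSpec(response="silt_deposits", family="binomial")
        with pytest.warns(UserWarning, match="excluded"):
            effects = fit_group_models(sites, strat, spec)
        assert {e.group for e in effects} == {0, 1, 3, 4}
        pooled = pool_estimates(effects)
        assert pooled.k == 4


class TestEstimatorFacade:
    def test_fit_and_pooled_attributes(self, default_sites):
        sites, truth, _ = default_sites
        fit = fit_propensity(sites, "arable_catch")
        strat = stratify(fit, 5)
        est = StratifiedEffectEstimator(
            spec=ModelSpec(response="nitrate", family="gaussian"))
        est.fit(sites, groups=strat.labels)
        assert len(est.group_effects_) == 5
        tr = truth.true_effects["nitrate"]
        assert abs(est.pooled_.estimate - tr) < 4 * est.pooled_.se

    def test_requires_groups(self, default_sites):
        sites, _, _ = default_sites
        est = StratifiedEffectEstimator(
            spec=ModelSpec(response="nitrate", family="gaussian"))
        with pytest.raises(ValueError, match="groups"):
            est.fit(sites)


class TestDirectModel:
    def test_agrees_with_propensity_when_unconfounded(self):
        cfg = GeneratorConfig(n_sites=2000, seed=55, confounding_strength=0.0)
        sites, _ = generate_sites(cfg)
        spec = ModelSpec(response="nitrate", family="gaussian")
        direct = fit_direct_model(sites, spec)
        fit = fit_propensity(sites, "arable_catch")
        strat = stratify(fit, 5)
        pooled = pool_estimates(fit_group_models(sites, strat, spec))
        assert abs(direct.estimate - pooled.estimate) < 2 * max(direct.se, pooled.se)


class TestTranslation:
    def test_log_odds_to_odds_multiplier(self):
        p = PooledEffect("silt", "binomial", 0.01386, se=0.001, k=5, n=100)
        out = translate_effect(p, delta=100)
        assert out["odds_multiplier"] == pytest.approx(np.exp(1.386), rel=1e-6)
        assert out["odds_multiplier"] == pytest.approx(4.00, abs=0.01)

    def test_zero_effect_is_identity(self):
        p = PooledEffect("silt", "binomial", 0.0, se=0.001, k=5, n=100)
        assert translate_effect(p, 100)["odds_multiplier"] == pytest.approx(1.0)
        g = PooledEffect("aspt", "gaussian", 0.0, se=0.001, k=5, n=100)
        assert translate_effect(g, 100)["difference"] == pytest.approx(0.0)

    def test_log10_chemistry_backtransform(self):
        p = PooledEffect("nitrate", "gaussian", 0.004, se=0.001, k=5, n=100)
        out = translate_effect(p, delta=100, baseline=2.0, scale="log10chem")
        assert out["difference"] == pytest.approx(2 * 10 ** 0.4 - 2, rel=1e-9)
        assert out["difference"] == pytest.approx(3.02, abs=0.01)

    def test_baseline_required_for_chemistry(self):
        p = PooledEffect("nitrate", "gaussian", 0.004, se=0.001, k=5, n=100)
        with pytest.raises(ValueError, match="baseline"):
            translate_effect(p, 100, scale="log10chem")

    def test_reference_baseline_near_intercept_value(self, default_sites):
        sites, _, _ = default_sites
        spec = ModelSpec(response="nitrate", family="gaussian")
        base = reference_baseline(sites, spec)
        # log10 nitrate at 0% cover, median covariates: near the generator's
        # intercept log10(2), well within the covariate amplitude
        assert abs(base - np.log10(2.0)) < 0.5


class TestSemivariogram:
    def test_iid_residuals_are_flat(self, rng):
        n = 300
        coords = rng.uniform(0, 100, size=(n, 2))
        resid = rng.normal(0, 2, n)
        sv = residual_semivariogram(resid, coords)
        assert sv.attrs["flat"]
        np.testing.assert_allclose(sv["gamma"], resid.var(), rtol=0.5)

    def test_spatial_trend_raises_gamma_with_distance(self, rng):
        n = 400
        coords = rng.uniform(0, 100, size=(n, 2))
        resid = 0.1 * coords[:, 0] + rng.normal(0, 0.3, n)
        sv = residual_semivariogram(resid, coords)
        assert not sv.attrs["flat"]
        assert sv["gamma"].iloc[-1] > 2 * sv["gamma"].iloc[0]

    def test_two_points_single_bin(self):
        sv = residual_semivariogram([1.0, 3.0], [[0, 0], [1, 1]])
        assert len(sv) == 1
        assert sv["gamma"].iloc[0] == pytest.approx((1 - 3) ** 2 / 2)

    def test_coincident_sites_rejected(self):
        with pytest.raises(ValueError, match="location"):
            residual_semivariogram([1.0, 2.0], [[5, 5], [5, 5]])
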