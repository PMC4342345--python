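"""Regression fits, stepwise AIC, and the bootstrap selection harness."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import permeascape as ps
from permeascape.models import (
    ModelDesign,
    anderson_darling,
    arcsine_sqrt,
    bootstrap_models,
    design_from_table,
    fit_linear,
    fit_logistic,
    percent_deviance,
    stepwise_aic,
)
from permeascape.types import ConfigurationError


class TestArcsineSqrt:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, math.pi / 2),
                                            (0.5, math.pi / 4)])
    def test_closed_form(self, p, expected):
        assert arcsine_sqrt(p) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            arcsine_sqrt(1.2)

    def test_vectorised_and_monotone(self):
        p = np.linspace(0, 1, 50)
        t = arcsine_sqrt(p)
        assert np.all(np.diff(t) > 0)
        assert t.min() >= 0 and t.max() <= math.pi / 2 + 1e-12


class TestAndersonDarling:
    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        a_star, _ = anderson_darling(x)
        a2_scipy = stats.anderson(x, "norm").statistic
        n = len(x)
        assert a_star == pytest.approx(a2_scipy * (1 + 0.75 / n + 2.25 / n**2),
                                       rel=1e-10)

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-5, 0.3, 50), rng.normal(5, 0.3, 50)])
        _, p = anderson_darling(x)
        assert p < 0.01

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        a1, p1 = anderson_darling(x)
        a2, p2 = anderson_darling(3.5 * x - 11.0)
        assert a1 == pytest.approx(a2, rel=1e-10)
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_gaussian_sample_not_rejected(self):
        rng = np.random.default_rng(3)
        _, p = anderson_darling(rng.normal(size=200))
        assert p > 0.05


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        d = ModelDesign(X=np.empty((4, 0)), y=np.array([0, 0, 1, 1.0]),
                        names=[], kind="logistic")
        fit = fit_logistic(d)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.deviance == pytest.approx(-2 * 4 * math.log(0.5), abs=1e-8)

    def test_intercept_only_23_47_split(self):
        y = np.array([0.0] * 23 + [1.0] * 47)
        fit = fit_logistic(ModelDesign(X=np.empty((70, 0)), y=y, names=[],
                                       kind="logistic"))
        assert fit.coef[0] == pytest.approx(math.log(47 / 23), abs=1e-8)

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.7, 0.2])))).astype(float)
        fit = fit_logistic(ModelDesign(X=X, y=y, names=["a", "b", "c"], kind="logistic"))
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, atol=1e-6)
        assert fit.deviance == pytest.approx(ref.deviance, abs=1e-6)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-6)

    def test_perfect_separation_flagged(self):
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)
        fit = fit_logistic(ModelDesign(X=X, y=y, names=["x"], kind="logistic"))
        assert fit.separated

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_logistic(ModelDesign(X=np.zeros((5, 1)), y=np.ones(5),
                                     names=["x"], kind="logistic"))


class TestFitLinear:
    def test_exact_linear_relationship(self):
        X = np.linspace(0, 1, 10).reshape(-1, 1)
        y = 3.0 + 2.0 * X[:, 0]
        fit = fit_linear(ModelDesign(X=X, y=y, names=["x"], kind="linear"))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coef == pytest.approx([3.0, 2.0])

    def test_pure_noise_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 4))
        y = rng.normal(size=500)
        fit = fit_linear(ModelDesign(X=X, y=y, names=list("abcd"), kind="linear"))
        assert abs(fit.adj_r2) < 0.05

    def test_matches_normal_equations_on_fixture(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 2.0], [5.0, 7.0]])
        y = np.array([2.0, 3.0, 7.0, 6.0, 11.0])
        Xd = np.column_stack([np.ones(5), X])
        expected = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        fit = fit_linear(ModelDesign(X=X, y=y, names=["a", "b"], kind="linear"))
        assert np.allclose(fit.coef, expected, atol=1e-10)

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 3))
        y = 1.0 + X @ [0.5, -1.0, 0.0] + rng.normal(0, 0.5, 60)
        fit = fit_linear(ModelDesign(X=X, y=y, names=["a", "b", "c"], kind="linear"))
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-8)
        assert np.allclose(fit.se, ref.bse, atol=1e-8)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-10)
        assert fit.f_pvalue == pytest.approx(ref.f_pvalue, abs=1e-10)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-6)

    def test_aliased_column_dropped(self):
        X = np.column_stack([np.arange(6.0), np.arange(6.0)])
        y = np.arange(6.0)
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_linear(ModelDesign(X=X, y=y, names=["a", "a2"], kind="linear"))
        assert np.isnan(fit.coef).sum() == 1


class TestStepwise:
    def test_signal_kept_noise_dropped(self):
        rng = np.random.default_rng(7)
        n = 70
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 2.0 * x1 + rng.normal(0, 0.1, n)
        d = ModelDesign(X=np.column_stack([x1, x2]), y=y, names=["x1", "x2"],
                        kind="linear")
        sel = stepwise_aic(d)
        assert sel.names == ["x1"]

    def test_identical_copies_collapse_to_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(0, 0.2, 50)
        X = np.column_stack([x, x, x])
        d = ModelDesign(X=X, y=y, names=["c1", "c2", "c3"], kind="linear")
        sel = stepwise_aic(d)
        assert len(sel.names) == 1

    def test_final_model_is_local_aic_optimum(self, segment_dataset):
        d = design_from_table(segment_dataset, "linear", width=3.0)
        full = ps.fit_linear(d)
        sel = stepwise_aic(d, full=full)
        assert sel.aic <= full.aic + 1e-9
        chosen = [d.names.index(nm) for nm in sel.names]
        # no single add or drop lowers AIC further
        for j in chosen:
            alt = ps.fit_linear(d.subset(cols=[c for c in chosen if c != j]))
            assert alt.aic >= sel.aic - 1e-6
        for j in range(len(d.names)):
            if j not in chosen:
                alt = ps.fit_linear(d.subset(cols=sorted(chosen + [j])))
                assert alt.aic >= sel.aic - 1e-6


class TestPercentDeviance:
    @pytest.mark.parametrize("resid,expected", [
        (75.112, 14.0),   # 3 m model
        (73.307, 16.1),   # 50 m model
        (62.455, 28.5),   # 400 m model
    ])
    def test_reproduces_reported_values(self, resid, expected):
        assert round(percent_deviance(87.350, resid), 1) == expected

    def test_equal_deviances_explain_nothing(self):
        assert percent_deviance(50.0, 50.0) == 0.0

    def test_zero_null_deviance_rejected(self):
        with pytest.raises(ValueError):
            percent_deviance(0.0, 0.0)


class TestBootstrap:
    def test_deterministic_given_seed(self, segment_dataset):
        d = design_from_table(segment_dataset, "logistic", width=3.0)
        a = bootstrap_models(d, B=30, retain=27, seed=42)
        b = bootstrap_models(d, B=30, retain=27, seed=42)
        assert np.array_equal(a.inclusion, b.inclusion)
        assert np.allclose(a.coefs, b.coefs, equal_nan=True)

    def test_strong_forest_effect_always_retained(self):
        df = ps.simulate_segment_dataset(
            n_segments=70, coefficients={"forest": 2.5}, noise_sd=0.2, seed=21,
        ).assign(width=3.0)
        d = design_from_table(df, "logistic", width=3.0)
        boot = bootstrap_models(d, B=100, retain=90, seed=1)
        assert boot.retention["forest"] == 100
        forest_betas = boot.coefs[:, 1 + d.names.index("forest")]
        assert np.all(forest_betas[~np.isnan(forest_betas)] > 0)
        assert "forest" in boot.selected

    def test_pure_noise_predictors_not_selected(self):
        ok = 0
        for rep in range(10):
            rng = np.random.default_rng(900 + rep)
            X = rng.normal(size=(70, 4))
            y = (rng.uniform(size=70) < 0.6).astype(float)
            d = ModelDesign(X=X, y=y, names=list("abcd"), kind="logistic")
            boot = bootstrap_models(d, B=100, retain=90, seed=rep)
            if not boot.selected:
                ok += 1
        assert ok >= 9

    def test_bootstrap_se_shrinks_with_sample_size(self):
        def se_at(n, seed):
            df = ps.simulate_segment_dataset(n_segments=n, seed=seed).assign(width=3.0)
            d = design_from_table(df, "linear", width=3.0)
            boot = bootstrap_models(d, B=60, retain=54, seed=seed)
            vt = boot.variable_table().set_index("variable")
            return vt.loc["grassland", "se_beta"]

        se70 = np.mean([se_at(70, s) for s in range(3)])
        se280 = np.mean([se_at(280, s) for s in range(3)])
        assert se280 < se70
        assert 1.2 < se70 / se280 < 3.5  # ~ sqrt(4) = 2 expected

    def test_variable_table_consistency(self, segment_dataset):
        d = design_from_table(segment_dataset, "logistic", width=3.0)
        boot = bootstrap_models(d, B=40, retain=36, seed=3)
        vt = boot.variable_table().set_index("variable")
        for name in d.names:
            ret = vt.loc[name, "retention"]
            assert 0 <= ret <= 40
            if ret > 0:
                assert vt.loc[name, "ci_lower"] <= vt.loc[name, "ci_upper"]
        stats_ = boot.fit_summary()
        assert stats_["mean_residual_deviance"] <= stats_["mean_null_deviance"]

    def test_selected_aic_never_above_full(self, segment_dataset):
        d = design_from_table(segment_dataset, "linear", width=3.0)
        full = ps.fit_linear(d)
        sel = stepwise_aic(d, full=full)
        assert sel.aic <= full.aic + 1e-9
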