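import numpy as np
import pandas as pd
import pytest

from plotspec import (
    LinearModel,
    ModelSpec,
    PLSRegressionCV,
    StepwiseAICRegressor,
    fit_ols,
    gaussian_aic,
    regression_metrics,
    repeated_evaluation,
    simulate_vi_yield_trial,
    stratified_split,
)
from plotspec.errors import CollinearityError, DegenerateFitError, InvalidConfigError, SplitError


class TestStratifiedSplit:
    def test_36_plot_design_splits_24_12(self):
        ids = np.arange(36)
        strata = np.repeat([0, 100, 200, 300], 9)
        train, test = stratified_split(ids, strata, seed=0)
        assert len(train) == 24 and len(test) == 12
        for level in (0, 100, 200, 300):
            assert np.sum(strata[train] == level) == 6
            assert np.sum(strata[test] == level) == 3

    def test_27_plot_nue_design_splits_18_9(self):
        ids = np.arange(27)
        strata = np.repeat([100, 200, 300], 9)
        train, test = stratified_split(ids, strata, seed=1)
        assert len(train) == 18 and len(test) == 9

    def test_partition_and_determinism(self):
        ids = np.arange(36)
        strata = np.repeat([0, 100, 200, 300], 9)
        a = stratified_split(ids, strata, seed=7)
        b = stratified_split(ids, strata, seed=7)
        assert a == b
        assert sorted(a[0] + a[1]) == list(ids)
        c = stratified_split(ids, strata, seed=8)
        assert c != a

    def test_small_stratum_rejected(self):
        with pytest.raises(SplitError):
            stratified_split([1, 2, 3], [0, 0, 100], seed=0)


class TestMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2, 3], [1.0, 2, 3])
        assert (m["r2"], m["rmse"], m["mae"]) == (1.0, 0.0, 0.0)

    def test_pure_offset_keeps_r2_one(self):
        m = regression_metrics([1.0, 2, 3], [3.0, 4, 5])
        assert m["r2"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(2.0)
        assert m["mae"] == pytest.approx(2.0)

    def test_hand_triple(self):
        m = regression_metrics([1.0, 2, 3], [1.0, 3, 2])
        assert m["rmse"] == pytest.approx(np.sqrt(2 / 3))
        assert m["mae"] == pytest.approx(2 / 3)

    def test_constant_actuals_warn_and_nan_r2(self):
        with pytest.warns(UserWarning):
            m = regression_metrics([2.0, 2, 2], [1.0, 2, 3])
        assert np.isnan(m["r2"]) and m["rmse"] > 0

    def test_rmse_at_least_mae_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, p = rng.normal(size=(2, 20))
            m = regression_metrics(a, p)
            assert m["rmse"] >= m["mae"] >= 0


class TestOls:
    def test_noiseless_interpolation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        beta = np.array([1.5, -2.0, 0.5])
        y = 4.0 + X @ beta
        model = fit_ols(X, y)
        np.testing.assert_allclose(model.coef_, beta, rtol=1e-10)
        assert model.intercept_ == pytest.approx(4.0)

    def test_closed_form_single_feature(self):
        model = fit_ols(np.array([0.0, 1, 2]), np.array([1.0, 3, 5]))
        assert model.intercept_ == pytest.approx(1.0)
        assert model.coef_[0] == pytest.approx(2.0)

    def test_duplicate_column_collinearity_named(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        with pytest.raises(CollinearityError) as err:
            fit_ols(X, np.array([1.0, 2, 3, 4]))
        assert "b" in err.value.columns

    def test_nested_model_train_rmse_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        y = X @ np.array([1.0, 0.5, 0, 0]) + rng.normal(0, 0.5, 40)
        full = fit_ols(X, y)
        sub = fit_ols(X[:, :2], y)
        assert full.rss_ <= sub.rss_ + 1e-12


class TestStepwise:
    def test_single_candidate_equals_ols_with_strong_signal(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(100, 1))
        y = 3 * x[:, 0] + rng.normal(0, 0.1, 100)
        sw = StepwiseAICRegressor().fit(x, y, feature_names=["x"])
        assert sw.selected_features_ == ["x"]
        np.testing.assert_allclose(sw.predict(x), fit_ols(x, y).predict(x), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_signal_always_selected(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(200, 5))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.1, 200)
        sw = StepwiseAICRegressor().fit(X, y, feature_names=list("abcde"))
        assert "a" in sw.selected_features_

    def test_final_aic_bounded_by_full_and_empty(self):
        rng = np.random.default_rng(4)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(50, 6))
            y = X @ rng.normal(size=6) * 0.3 + rng.normal(size=50)
            sw = StepwiseAICRegressor().fit(X, y)
            assert sw.aic_ <= sw.aic_full_ + 1e-9
            assert sw.aic_ <= sw.aic_empty_ + 1e-9

    def test_pure_noise_prefers_small_models(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 5))
        y = rng.normal(size=200)
        sw = StepwiseAICRegressor().fit(X, y)
        assert len(sw.selected_features_) <= 2

    def test_gaussian_aic_formula(self):
        assert gaussian_aic(10.0, 20, 3) == pytest.approx(20 * np.log(0.5) + 8)


class TestPlsr:
    def test_univariate_one_component_equals_simple_regression(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 1))
        y = 2 * x[:, 0] + rng.normal(0, 0.3, 30)
        pls = PLSRegressionCV(n_components=1).fit(x, y)
        ols = fit_ols(x, y)
        np.testing.assert_allclose(pls.predict(x), ols.predict(x), atol=1e-10)

    def test_full_components_equal_ols(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.2, 40)
        pls = PLSRegressionCV(n_components=6).fit(X, y)
        ols = fit_ols(X, y)
        assert np.abs(pls.predict(X) - ols.predict(X)).max() < 1e-8

    def test_ncomp_above_rank_rejected(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0) * 2])
        with pytest.raises(DegenerateFitError):
            PLSRegressionCV(n_components=2).fit(X, np.arange(10.0))

    @pytest.mark.parametrize("seed", range(30))
    def test_cv_finds_low_dimensional_latent_structure(self, seed):
        # y depends on one latent direction of a 9-feature X
        rng = np.random.default_rng(seed)
        t = rng.normal(size=60)
        loadings = rng.normal(size=9)
        X = np.outer(t, loadings) + rng.normal(0, 0.3, size=(60, 9))
        y = 2.0 * t + rng.normal(0, 0.3, 60)
        pls = PLSRegressionCV(n_components="cv", random_state=seed).fit(X, y)
        assert pls.n_components_ <= 3


class TestModelSpec:
    def test_lr_requires_exactly_one_feature(self):
        with pytest.raises(InvalidConfigError):
            ModelSpec(family="lr", features="all")
        with pytest.raises(InvalidConfigError):
            ModelSpec(family="lr", features=["a", "b"])

    def test_unknown_family_rejected(self):
        with pytest.raises(InvalidConfigError):
            ModelSpec(family="rf")


class TestRepeatedEvaluation:
    def _tables(self, noise_sd=0.0, seed=0):
        vi, traits, _ = simulate_vi_yield_trial(seed=seed, population_r2=0.85)
        if noise_sd == 0.0:
            traits = traits.copy()
            traits["yield_kg_ha"] = 1000 + 500 * vi["value"].to_numpy()
        return vi, traits

    @pytest.mark.parametrize("family", ["lr", "mlr", "smlr", "plsr"])
    def test_noiseless_linear_target_is_perfect(self, family):
        vi, traits = self._tables(noise_sd=0.0)
        features = ["repRVI@LGF"] if family == "lr" else "all"
        spec = ModelSpec(family=family, features=features, target="yield")
        s = repeated_evaluation(spec, vi, traits, base_seed=0)
        assert not s.failures
        agg = s.aggregate()
        assert agg.loc["test_r2", "mean"] == pytest.approx(1.0, abs=1e-9)
        assert agg.loc["test_rmse", "mean"] == pytest.approx(0.0, abs=1e-6)
        assert agg.loc["test_r2", "std"] == pytest.approx(0.0, abs=1e-9)

    def test_same_base_seed_reproduces_summary(self):
        vi, traits, _ = simulate_vi_yield_trial(seed=1)
        spec = ModelSpec(family="lr", features=["repRVI@LGF"], target="yield")
        a = repeated_evaluation(spec, vi, traits, base_seed=5).per_repeat
        b = repeated_evaluation(spec, vi, traits, base_seed=5).per_repeat
        pd.testing.assert_frame_equal(a, b)

    def test_families_share_split_seeds(self):
        vi, traits, _ = simulate_vi_yield_trial(seed=2)
        a = repeated_evaluation(
            ModelSpec(family="lr", features=["repRVI@LGF"]), vi, traits, base_seed=3
        ).per_repeat
        b = repeated_evaluation(
            ModelSpec(family="mlr", features=["repRVI@LGF"]), vi, traits, base_seed=3
        ).per_repeat
        assert (a["seed"] == b["seed"]).all()
        # same single feature, same splits -> identical OLS results
        np.testing.assert_allclose(a["test_rmse"], b["test_rmse"], rtol=1e-10)

    def test_standardization_affine_equivariance(self):
        vi, traits, _ = simulate_vi_yield_trial(seed=4)
        spec = ModelSpec(family="mlr", features=["repRVI@LGF"], target="yield")
        base = repeated_evaluation(spec, vi, traits, base_seed=0).per_repeat
        vi2 = vi.copy()
        vi2["value"] = 10.0 * vi2["value"] + 3.0
        shifted = repeated_evaluation(spec, vi2, traits, base_seed=0).per_repeat
        np.testing.assert_allclose(base["test_rmse"], shifted["test_rmse"], rtol=1e-8)
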