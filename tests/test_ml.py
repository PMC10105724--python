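"""Covariate -> kinetics-parameter prediction workflow."""

import numpy as np
import pandas as pd
import pytest

from somkin import ml
from somkin.synthetic import SyntheticConfig, gen_covariates


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(0)
    X = gen_covariates(SyntheticConfig(n_sites=200), seed=0)[ml.COVARIATES]
    y = 0.002 * X["MAP"].to_numpy() + 0.1 * X["pH"].to_numpy() \
        + rng.normal(0, 1e-4, len(X))
    return X, y


class TestPartition:
    def test_split_contract(self, linear_data):
        X, y = linear_data
        Xtr, Xte, ytr, yte, tr, te = ml.partition(X, y, 0.75, seed=1)
        assert len(tr) == 150 and len(te) == 50
        assert set(tr) & set(te) == set()
        assert sorted(np.concatenate([tr, te])) == list(range(200))

    def test_determinism(self, linear_data):
        X, y = linear_data
        a = ml.partition(X, y, 0.75, seed=7)[4]
        b = ml.partition(X, y, 0.75, seed=7)[4]
        np.testing.assert_array_equal(a, b)

    def test_stratification_covers_modes(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(10, 0.1, 50)])
        X = pd.DataFrame({"a": rng.normal(size=100)})
        for seed in range(50):
            _, _, ytr, yte, _, _ = ml.partition(X, y, 0.75, seed=seed)
            assert (ytr > 5).any() and (ytr < 5).any()
            assert (yte > 5).any() and (yte < 5).any()

    def test_small_sample_fallback_warns(self):
        X = pd.DataFrame({"a": np.arange(8.0)})
        with pytest.warns(UserWarning, match="stratification"):
            ml.partition(X, np.arange(8.0), 0.75, seed=0)


class TestRFE:
    def test_recovers_informative_features(self):
        X = gen_covariates(SyntheticConfig(n_sites=250), seed=5)[ml.COVARIATES]
        y = np.tanh(3 * (X["Sand"] / 100 - 0.5)) + np.sin(X["MBC"] / 200)
        sel, profile = ml.rfe_select(X, y.to_numpy(), method="rf", folds=5,
                                     seed=0)
        assert {"Sand", "MBC"} <= set(sel)
        assert len(profile) == 11 and list(profile["size"]) == list(range(1, 12))

    def test_pure_noise_returns_smallest_subset(self):
        rng = np.random.default_rng(3)
        X = gen_covariates(SyntheticConfig(n_sites=150), seed=3)[ml.COVARIATES]
        sel, _ = ml.rfe_select(X, rng.normal(size=150), method="rf", folds=4,
                               seed=0)
        assert len(sel) == 1

    def test_constant_target_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="constant"):
            ml.rfe_select(X, np.ones(4), method="mlr", folds=2)


class TestTraining:
    def test_mlr_matches_linear_truth(self, linear_data):
        X, y = linear_data
        m = ml.train_model(X, y, method="mlr", rfe=False, seed=0, cv_folds=3,
                           cv_repeats=1)
        assert m.train_metrics["r2"] > 0.999
        assert m.test_metrics["r2"] > 0.999

    def test_gbm_grid_cell_count(self, linear_data):
        X, y = linear_data
        reg = ml.KineticsParameterRegressor(method="gbm", rfe=False,
                                            cv_folds=3, cv_repeats=1,
                                            random_state=0)
        # contract: |n.trees grid| x 7 depths x 2 shrinkages, min node size 10
        assert len(ml.DEFAULT_GBM_GRID["n_estimators"]) * \
            len(ml.DEFAULT_GBM_GRID["max_depth"]) * \
            len(ml.DEFAULT_GBM_GRID["learning_rate"]) == 70
        assert ml.DEFAULT_GBM_GRID["min_samples_leaf"] == [10]

    def test_log10_transform_round_trip(self, k3_training_data):
        X, y = k3_training_data
        reg = ml.KineticsParameterRegressor(
            method="mlr", rfe=False, target_transform="log10", cv_folds=3,
            random_state=0).fit(X, y)
        pred = reg.predict(X)
        assert (pred > 0).all()

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0, 4.0]})
        reg = ml.KineticsParameterRegressor(method="mlr", rfe=False)
        with pytest.raises(ValueError, match="missing"):
            reg.fit(X, np.arange(4.0))

    def test_repeat_and_select_contract(self, linear_data):
        X, y = linear_data
        best, hist = ml.repeat_and_select(X, y, method="mlr", n_repeats=3,
                                          seed=1, rfe=False, cv_folds=3,
                                          cv_repeats=1)
        assert len(hist) == 3
        assert best.test_metrics["r2"] == pytest.approx(hist["test_r2"].max())


class TestModelSelection:
    def test_aic_prefers_fewer_features_at_equal_sse(self):
        assert ml._metrics.aic_sse(2.0, 2, 1) < ml._metrics.aic_sse(2.0, 2, 2)

    def test_compare_by_aic_ranks_and_validates(self, linear_data):
        X, y = linear_data
        a = ml.train_model(X, y, method="mlr", rfe=False, seed=4, cv_folds=3,
                           cv_repeats=1)
        b = ml.train_model(X, y, method="rf", rfe=False, seed=4, cv_folds=3,
                           cv_repeats=1, grid={"max_features": [3]})
        ranked = ml.compare_by_aic([a, b])
        assert ranked[0].aic <= ranked[1].aic
        assert [m.aic for m in ml.compare_by_aic([b, a])] == \
            [m.aic for m in ranked]
        c = ml.train_model(X, y, method="mlr", rfe=False, seed=5, cv_folds=3,
                           cv_repeats=1)
        with pytest.raises(ValueError, match="different observation sets"):
            ml.compare_by_aic([a, c])


class TestImportance:
    def test_sums_to_100_and_nonnegative(self, fitted_rf):
        imp = ml.variable_importance(fitted_rf, seed=0)
        assert imp.sum() == pytest.approx(100.0, abs=1e-6)
        assert (imp >= 0).all()
        assert set(imp.index) == set(ml.COVARIATES)

    def test_single_feature_gets_100(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"pH": rng.uniform(4, 9, 100)})
        y = X["pH"].to_numpy() * 2 + rng.normal(0, 0.01, 100)
        reg = ml.KineticsParameterRegressor(method="mlr", rfe=False,
                                            cv_folds=3).fit(X, y)
        imp = reg.feature_importance(X, y)
        assert imp["pH"] == pytest.approx(100.0)

    def test_null_feature_scores_low(self, fitted_rf):
        # IncT never enters the generating map for the passive-pool rate
        imp = ml.variable_importance(fitted_rf, seed=0)
        assert imp["IncT"] < 10.0
        assert imp.idxmax() == "pH"


class TestPartialDependence:
    def test_grid_contract_and_normalization(self, fitted_rf):
        curve = ml.partial_dependence(fitted_rf, fitted_rf.X_test, "pH",
                                      grid_size=15)
        assert len(curve) == 15
        assert curve["x_norm"].iloc[0] == 0.0
        assert curve["x_norm"].iloc[-1] == 1.0

    def test_flat_for_constant_prediction(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 60),
                          "b": rng.uniform(0, 1, 60)})
        y = np.full(60, 5.0) + rng.normal(0, 1e-9, 60)
        reg = ml.KineticsParameterRegressor(method="mlr", rfe=False,
                                            cv_folds=3).fit(X, y)
        curve = ml.partial_dependence(reg, X, "a", grid_size=10)
        assert curve["yhat"].std() < 1e-6

    def test_linear_additive_map_recovered(self):
        """For an additive linear truth fitted by MLR, the PD curve equals the
        component up to its additive constant."""
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 300),
                          "b": rng.uniform(0, 1, 300)})
        y = 3.0 * X["a"].to_numpy() - 2.0 * X["b"].to_numpy() \
            + rng.normal(0, 1e-6, 300)
        reg = ml.KineticsParameterRegressor(method="mlr", rfe=False,
                                            cv_folds=3).fit(X, y)
        curve = ml.partial_dependence(reg, X, "a", grid_size=11)
        comp = 3.0 * curve["x"].to_numpy()
        resid = curve["yhat"].to_numpy() - comp
        rng_y = comp.max() - comp.min()
        assert np.std(resid) < 0.05 * rng_y

    def test_errors(self, fitted_rf):
        with pytest.raises(ValueError, match="not among"):
            ml.partial_dependence(fitted_rf, fitted_rf.X_test, "nope")
        Xc = fitted_rf.X_test.copy()
        Xc["pH"] = 7.0
        with pytest.raises(ValueError, match="constant"):
            ml.partial_dependence(fitted_rf, Xc, "pH")
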