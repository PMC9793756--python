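"""PLS1 core: fit/predict contracts, metrics, and MCCV behavior, each
checked against an independent oracle (ordinary least squares, sklearn's
NIPALS, or a hand-stepped computation)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gwopls import (
    CVConfig,
    draw_mccv_splits,
    fit_pls,
    mccv_rmsecv,
    predict,
    r_squared,
    rmse,
    select_n_lv,
)


def _ols_coef(X, y):
    """Normal-equations oracle on centered data."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return np.linalg.lstsq(Xc, yc, rcond=None)[0]


class TestFitPredict:
    def test_exact_linear_relation_single_column(self):
        model = fit_pls(np.array([[1.0], [2.0], [3.0]]), [2.0, 4.0, 6.0], 1)
        assert model.coefficients[0] == pytest.approx(2.0)
        # intercept via centering: y_mean - x_mean @ b = 4 - 2*2 = 0
        assert model.y_mean - model.x_mean @ model.coefficients == pytest.approx(0.0)

    @pytest.mark.parametrize("shape", [(8, 3), (10, 5), (7, 2)])
    def test_full_rank_pls_equals_ols(self, shape):
        rng = np.random.default_rng(sum(shape))
        X = rng.normal(size=shape)
        y = rng.normal(size=shape[0]) * 3 + 1
        model = fit_pls(X, y, n_lv=shape[1])
        np.testing.assert_allclose(model.coefficients, _ols_coef(X, y), atol=1e-8)
        np.testing.assert_allclose(
            predict(model, X), X @ _ols_coef(X, y) - X.mean(0) @ _ols_coef(X, y) + y.mean(),
            atol=1e-8,
        )

    def test_agrees_with_sklearn_nipals(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 12))
        y = X[:, 0] - 0.5 * X[:, 3] + 0.1 * rng.normal(size=20)
        for k in (1, 2, 4):
            ours = fit_pls(X, y, k).coefficients
            ref = sklearn_pls.PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(ours, np.ravel(ref.coef_), atol=1e-8)

    def test_constant_column_gets_zero_weight(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 4))
        X[:, 2] = 7.0
        model = fit_pls(X, rng.normal(size=12) + 5, 3)
        assert np.all(np.abs(model.weights[2]) < 1e-12)
        assert model.coefficients[2] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_x_predicts_mean(self):
        y = np.array([1.0, 3.0, 5.0, 7.0])
        model = fit_pls(np.zeros((4, 3)), y, 1)
        np.testing.assert_allclose(predict(model, np.zeros((2, 3))), y.mean())

    def test_single_sample_prediction(self):
        model = fit_pls(np.array([[1.0], [2.0], [3.0]]), [2.0, 4.0, 6.0], 1)
        assert predict(model, [[5.0]]).shape == (1,)

    def test_error_contracts(self):
        X = np.arange(6.0).reshape(3, 2)
        with pytest.raises(ValueError):
            fit_pls(X, [1.0, 2.0], 1)  # length mismatch
        with pytest.raises(ValueError):
            fit_pls(X, [1.0, 2.0, 3.0], 5)  # n_lv out of range
        with pytest.raises(ValueError):
            fit_pls(X, [2.0, 2.0, 2.0], 1)  # zero-variance y
        model = fit_pls(X, [1.0, 2.0, 3.0], 1)
        with pytest.raises(ValueError):
            predict(model, np.ones((2, 3)))  # column mismatch


class TestMetrics:
    def test_rmse_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
        with pytest.raises(ValueError):
            rmse([], [])

    def test_rmse_matches_elementwise_loop(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=100), rng.normal(size=100)
        acc = 0.0
        for x, z in zip(a, b):
            acc += (x - z) ** 2
        assert rmse(a, b) == pytest.approx(np.sqrt(acc / 100), abs=1e-12)

    def test_r_squared_examples(self):
        y = np.array([1.0, 2.0, 4.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0], [1.0, 3.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=30), st.integers(0, 10**6))
    def test_metric_bounds(self, y_true, seed):
        y_true = np.asarray(y_true)
        y_pred = y_true + np.random.default_rng(seed).normal(size=y_true.size)
        assert rmse(y_true, y_pred) >= 0.0
        if np.ptp(y_true) > 1e-9:
            r2 = r_squared(y_true, y_pred)
            assert r2 <= 1.0
            # R^2 hits 1 only with all-zero residuals
            assert (r2 == 1.0) == np.allclose(y_true, y_pred)


class TestMCCV:
    def test_noise_free_linear_target(self, light_cv):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = 2.0 * X[:, 1] + 10
        # masked down to the single informative column the model is exact
        assert mccv_rmsecv(X[:, [1]], y, 1, light_cv) < 1e-8

    def test_deterministic_for_fixed_seed(self, light_cv):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=25)
        assert mccv_rmsecv(X, y, 3, light_cv) == mccv_rmsecv(X, y, 3, light_cv)

    def test_single_split_matches_hand_computation(self):
        """n_splits=1 on a 2-column full-rank problem equals manually
        fitting centered least squares on the calibration half."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 2))
        y = X @ [1.5, -2.0] + 0.2 * rng.normal(size=20)
        cv = CVConfig(n_splits=1, calibration_fraction=0.7, seed=42)
        (cal, val), = draw_mccv_splits(20, cv)
        b = np.linalg.lstsq(X[cal] - X[cal].mean(0), y[cal] - y[cal].mean(), rcond=None)[0]
        pred = (X[val] - X[cal].mean(0)) @ b + y[cal].mean()
        expected = np.sqrt(np.mean((pred - y[val]) ** 2))
        assert mccv_rmsecv(X, y, 2, cv) == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_sample_relabeling(self, light_cv):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(24, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=24)
        splits = draw_mccv_splits(24, light_cv)
        ref = mccv_rmsecv(X, y, 2, light_cv, splits=splits)
        perm = rng.permutation(24)
        inv = np.argsort(perm)
        mapped = [(np.sort(inv[c]), np.sort(inv[v])) for c, v in splits]
        assert mccv_rmsecv(X[perm], y[perm], 2, light_cv, splits=mapped) == pytest.approx(ref, abs=1e-12)

    def test_noisier_targets_raise_median_rmsecv(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 10))
        signal = X @ rng.normal(size=10)
        cv = CVConfig(n_splits=10, seed=0)
        medians = []
        for sd in (0.1, 1.0, 3.0):
            vals = [
                mccv_rmsecv(X, signal + sd * np.random.default_rng(s).normal(size=40), 5, cv)
                for s in range(20)
            ]
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]

    def test_infeasible_lv_is_clamped_with_warning(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(8, 10))
        y = rng.normal(size=8) + 5
        cv = CVConfig(n_splits=3, calibration_fraction=0.5, seed=0)
        with pytest.warns(UserWarning, match="clamped"):
            value = mccv_rmsecv(X, y, 6, cv)  # 4 calibration samples support <= 3 LVs
        assert np.isfinite(value)


class TestSelectNLV:
    def test_recovers_two_latent_directions(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            T = rng.normal(size=(60, 2))
            X = T @ rng.normal(size=(2, 15)) + 0.01 * rng.normal(size=(60, 15))
            y = T @ [2.0, -1.0] + 0.01 * rng.normal(size=60)
            if select_n_lv(X, y, 6, CVConfig(n_splits=15, seed=s)) == 2:
                hits += 1
        assert hits >= 8

    def test_single_candidate(self, light_cv):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 4))
        y = X[:, 0] + rng.normal(size=15)
        assert select_n_lv(X, y, 1, light_cv) == 1
        with pytest.raises(ValueError):
            select_n_lv(X, y, 0, light_cv)
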