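import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utr5xpress.evaluation import (
    CVScheme,
    ablation_study,
    bias_slopes,
    binned_abs_error,
    pearson_r,
    run_cv,
)


class _Oracle:
    """Predicts the training mean unless memorizing; used to probe CV plumbing."""

    def fit(self, X, y):
        self.X = np.asarray(X)
        self.y = np.asarray(y)
        return self

    def predict(self, X):
        X = np.asarray(X)
        # nearest-neighbor lookup: exact for test rows drawn from the same data
        out = np.empty(len(X))
        for i, row in enumerate(X):
            j = np.argmin(np.sum((self.X - row) ** 2, axis=1))
            out[i] = self.y[j]
        return out


class _TrueModel:
    """Knows the generating function: predict = first feature."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.asarray(X)[:, 0]


class TestPearson:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=20)
        assert pearson_r(x, x) == 1.0
        assert pearson_r(x, -x) == -1.0

    def test_hand_computed_example(self):
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=1e-4)

    def test_matches_scipy(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=(2, 30))
            assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_affine_invariance_positive_scale(self, rng):
        x, y = rng.normal(size=(2, 25))
        assert pearson_r(3.2 * x + 1, y) == pytest.approx(pearson_r(x, y), abs=1e-12)

    def test_zero_variance_is_error_not_nan(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2, 3])


class TestRunCV:
    def _data(self, rng, n=50):
        X = rng.normal(size=(n, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=n)
        return X, y

    def test_fold_sizes_balanced_and_partition(self, rng):
        X, y = self._data(rng, 53)
        calls = []

        class Recorder(_TrueModel):
            def predict(self, Xt):
                calls.append(len(Xt))
                return super().predict(Xt)

        run_cv(Recorder, X, y, CVScheme(folds=10, seed=0))
        assert sum(calls) == 53
        assert max(calls) - min(calls) <= 1

    def test_true_model_scores_near_one(self, rng):
        X, y = self._data(rng)
        report = run_cv(_TrueModel, X, y, CVScheme(folds=5))
        assert report.mean_r > 0.99

    def test_oracle_lookup_scores_one(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        report = run_cv(_Oracle, X, np.arange(40.0), CVScheme(folds=5))
        # nearest-neighbor on the training fold cannot see test rows -> not 1;
        # but an oracle predicting y exactly must give 1:

        class Exact:
            def fit(self, X_, y_):
                return self

            def predict(self, X_):
                # recover indices by matching rows against the full matrix
                idx = [np.argmin(np.sum((X - r) ** 2, axis=1)) for r in np.asarray(X_)]
                return np.arange(40.0)[idx]

        report = run_cv(Exact, X, np.arange(40.0), CVScheme(folds=5))
        assert report.mean_r == pytest.approx(1.0)
        assert report.pooled_r == pytest.approx(1.0)

    def test_standard_mode_deterministic(self, rng):
        X, y = self._data(rng)
        r1 = run_cv(_TrueModel, X, y, CVScheme(mode="standard", folds=5, seed=4))
        r2 = run_cv(_TrueModel, X, y, CVScheme(mode="standard", folds=5, seed=4))
        assert r1.per_fold_r == r2.per_fold_r

    def test_randomized_mode_repeats_folds(self, rng):
        X, y = self._data(rng)
        report = run_cv(
            _TrueModel, X, y, CVScheme(mode="randomized", folds=5, seed=4, repetitions=3)
        )
        assert len(report.per_fold_r) == 15

    def test_n_smaller_than_folds_rejected(self, rng):
        X, y = self._data(rng, 5)
        with pytest.raises(ValueError):
            run_cv(_TrueModel, X, y, CVScheme(folds=10))


class TestBinnedError:
    def test_perfect_predictions_zero_everywhere(self):
        obs = np.array([0.5, 1.5, 2.5])
        out = binned_abs_error(obs, obs, edges=[0, 1, 2, 3])
        assert set(out.values()) == {0.0}

    def test_single_bin_is_overall_mae(self, rng):
        obs = rng.normal(size=30)
        pred = obs + rng.normal(size=30)
        out = binned_abs_error(pred, obs, edges=[-100, 100])
        assert out[(-100.0, 100.0)] == pytest.approx(np.mean(np.abs(pred - obs)))

    def test_hand_built_case(self):
        obs = np.array([0.2, 0.8, 1.5, 1.9])
        pred = np.array([0.4, 0.4, 2.0, 1.0])
        out = binned_abs_error(pred, obs, edges=[0, 1, 2])
        assert out[(0.0, 1.0)] == pytest.approx((0.2 + 0.4) / 2)
        assert out[(1.0, 2.0)] == pytest.approx((0.5 + 0.9) / 2)

    def test_empty_bins_absent(self):
        out = binned_abs_error([1.0], [0.5], edges=[0, 1, 2, 3])
        assert (1.0, 2.0) not in out
        assert (2.0, 3.0) not in out

    def test_nonincreasing_edges_rejected(self):
        with pytest.raises(ValueError):
            binned_abs_error([1.0], [1.0], edges=[0, 0, 1])


class TestBiasSlopes:
    def test_perfect_predictor(self, rng):
        obs = rng.normal(size=40)
        out = bias_slopes(obs, obs)
        assert out["slope_pred_vs_actual"] == pytest.approx(1.0)
        assert out["slope_error_vs_actual"] == pytest.approx(0.0)

    def test_constant_predictor(self, rng):
        obs = rng.normal(size=40)
        out = bias_slopes(np.full(40, obs.mean()), obs)
        assert out["slope_pred_vs_actual"] == pytest.approx(0.0)
        assert out["slope_error_vs_actual"] == pytest.approx(-1.0)

    def test_shrunken_predictions(self, rng):
        obs = rng.normal(size=40)
        out = bias_slopes(0.5 * obs, obs)
        assert out["slope_pred_vs_actual"] == pytest.approx(0.5)
        assert out["slope_error_vs_actual"] == pytest.approx(-0.5)

    def test_slope_identity_exact(self, rng):
        pred, obs = rng.normal(size=(2, 30))
        out = bias_slopes(pred, obs)
        assert out["slope_error_vs_actual"] == out["slope_pred_vs_actual"] - 1.0


class TestAblation:
    def _frame(self, rng, n=60):
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["a", "b", "c", "d"])
        y = X["a"].to_numpy() + 0.05 * rng.normal(size=n)
        return X, y

    def test_same_subset_twice_identical(self, rng):
        from sklearn.tree import DecisionTreeRegressor

        X, y = self._frame(rng)
        factory = lambda: DecisionTreeRegressor(random_state=0)
        table = ablation_study(
            X, y, {"full": list(X.columns), "again": list(X.columns)}, factory, CVScheme(folds=5)
        )
        assert table["mean_r"].nunique() == 1

    def test_informative_subset_wins(self, rng):
        from sklearn.tree import DecisionTreeRegressor

        X, y = self._frame(rng)
        factory = lambda: DecisionTreeRegressor(random_state=0)
        table = ablation_study(
            X, y, {"with_a": ["a", "b"], "without_a": ["b", "c", "d"]}, factory, CVScheme(folds=5)
        )
        assert table.iloc[0]["subset"] == "with_a"

    def test_empty_subset_rejected(self, rng):
        X, y = self._frame(rng)
        with pytest.raises(ValueError):
            ablation_study(X, y, {"empty": []}, lambda: None)

    def test_one_row_per_subset(self, rng):
        from sklearn.tree import DecisionTreeRegressor

        X, y = self._frame(rng)
        table = ablation_study(
            X,
            y,
            {"s1": ["a"], "s2": ["b"], "s3": ["c", "d"]},
            lambda: DecisionTreeRegressor(random_state=0),
            CVScheme(folds=5),
        )
        assert len(table) == 3
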