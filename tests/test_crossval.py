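import numpy as np
import pandas as pd
import pytest

from connpredict import rvr
from connpredict.crossval import (encode_covariates, fit_fold, kfold_indices,
                                  minmax_scale_fold, prediction_accuracy,
                                  run_loocv, run_repeated_kfold)


def toy_phenotypes(y, **extra):
    n = len(y)
    base = {"subject": [f"sub-{i:03d}" for i in range(n)], "psqi": y,
            "age": np.linspace(20, 60, n), "sex": ["M", "F"] * (n // 2) +
            ["M"] * (n % 2), "education": np.linspace(8, 18, n)}
    base.update(extra)
    return pd.DataFrame(base)


class TestMinMaxScaling:
    def test_basic_column_scaled_to_unit_interval(self):
        train = np.array([[2.0], [4.0], [6.0]])
        tr, te = minmax_scale_fold(train, np.array([[8.0]]))
        np.testing.assert_array_equal(tr.ravel(), [0.0, 0.5, 1.0])
        assert te[0, 0] == 1.5  # extrapolation retained, no clipping

    def test_zero_range_feature_maps_to_zero(self):
        train = np.array([[3.0, 1.0], [3.0, 2.0]])
        test = np.array([[7.0, 1.5]])
        tr, te = minmax_scale_fold(train, test)
        assert np.all(tr[:, 0] == 0.0) and te[0, 0] == 0.0
        assert te[0, 1] == 0.5

    def test_matches_two_pass_oracle(self, rng):
        train = rng.normal(5, 2, (20, 10))
        test = rng.normal(5, 2, (5, 10))
        tr, te = minmax_scale_fold(train, test)
        # independently coded two-pass computation
        for j in range(10):
            lo = min(train[i, j] for i in range(20))
            hi = max(train[i, j] for i in range(20))
            for i in range(20):
                assert tr[i, j] == (train[i, j] - lo) / (hi - lo)
            for i in range(5):
                assert te[i, j] == (test[i, j] - lo) / (hi - lo)


class TestPredictionAccuracy:
    def test_perfect_prediction(self, rng):
        y = rng.normal(15, 3, 20)
        Z = rng.normal(size=(20, 2))
        m = prediction_accuracy(y, y, Z)
        assert m["r"] == pytest.approx(1.0)
        assert m["partial_r"] == pytest.approx(1.0)
        assert m["mae"] == 0.0

    def test_constant_bias_shows_in_mae_not_r(self, rng):
        y = rng.normal(15, 3, 20)
        m = prediction_accuracy(y, y + 2.0)
        assert m["r"] == pytest.approx(1.0)
        assert m["mae"] == pytest.approx(2.0)

    def test_partial_r_matches_textbook_recursion(self, rng):
        """Single-covariate partial correlation equals
        (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        n = 12
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.3 * z + rng.normal(size=n)
        m = prediction_accuracy(x, y, z[:, None])
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert m["partial_r"] == pytest.approx(oracle, abs=1e-12)

    def test_too_few_subjects_after_adjustment_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 3"):
            prediction_accuracy(np.arange(4.0), np.arange(4.0), rng.normal(size=(4, 2)))


class TestEncodeCovariates:
    def test_sex_codes_normalised(self):
        ph = toy_phenotypes(np.arange(6))
        Z = encode_covariates(ph, ["sex"])
        np.testing.assert_array_equal(Z.ravel(), [0, 1, 0, 1, 0, 1])

    def test_numeric_binary_sex(self):
        ph = toy_phenotypes(np.arange(4))
        ph["sex"] = ["0", "1", "1", "0"]
        np.testing.assert_array_equal(
            encode_covariates(ph, ["sex"]).ravel(), [0, 1, 1, 0])

    def test_multilevel_category_one_hot_drops_first(self):
        ph = toy_phenotypes(np.arange(6), site=["a", "b", "c", "a", "b", "c"])
        Z = encode_covariates(ph, ["site"])
        assert Z.shape == (6, 2)  # 3 levels -> 2 columns

    def test_missing_column_named(self):
        ph = toy_phenotypes(np.arange(6))
        with pytest.raises(KeyError, match="'motion'"):
            encode_covariates(ph, ["motion"])


class TestLOOCV:
    def test_oracle_feature_predicts_almost_perfectly(self, rng):
        y = rng.normal(15, 3, 20)
        X = np.column_stack([y + rng.normal(0, 0.01, 20),
                             rng.normal(size=20)])
        cv = run_loocv(X, toy_phenotypes(y), ["age", "sex", "education"])
        assert cv.metrics["r"] > 0.99
        assert cv.metrics["mae"] < 0.5

    def test_fold_bookkeeping_micro_cohort(self, rng):
        """n=6: each subject tested exactly once, trained on the other 5."""
        y = rng.normal(15, 3, 6)
        X = rng.uniform(0, 1, (6, 3))
        cv = run_loocv(X, toy_phenotypes(y))
        np.testing.assert_array_equal(cv.fold_assignment, np.arange(6))
        assert cv.observed.shape == cv.predicted.shape == (6,)
        assert not np.isnan(cv.predicted).any()
        # manual enumeration of fold 2
        model, pred = fit_fold(X, y, np.array([0, 1, 3, 4, 5]), np.array([2]))
        assert pred[0] == cv.predicted[2]

    def test_loocv_deterministic(self, rng):
        y = rng.normal(15, 3, 10)
        X = rng.uniform(0, 1, (10, 4))
        ph = toy_phenotypes(y)
        a = run_loocv(X, ph)
        b = run_loocv(X, ph)
        np.testing.assert_array_equal(a.predicted, b.predicted)


class TestRepeatedKFold:
    def test_k_equals_n_reproduces_loocv(self, rng):
        y = rng.normal(15, 3, 12)
        X = np.column_stack([y + rng.normal(0, 0.1, 12), rng.normal(size=12)])
        ph = toy_phenotypes(y)
        loo = run_loocv(X, ph)
        kf = run_repeated_kfold(X, ph, k=12, repeats=1, seed=5)
        np.testing.assert_allclose(kf.predicted, loo.predicted, atol=1e-12)

    def test_deterministic_given_seed(self, rng):
        y = rng.normal(15, 3, 15)
        X = rng.uniform(0, 1, (15, 4))
        ph = toy_phenotypes(y)
        a = run_repeated_kfold(X, ph, k=5, repeats=3, seed=9)
        b = run_repeated_kfold(X, ph, k=5, repeats=3, seed=9)
        assert a.metrics == b.metrics
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_fold_sizes_near_equal(self):
        idx = kfold_indices(23, 10, seed=1, repeat=0)
        sizes = sorted(len(te) for _, te in idx)
        assert sizes == [2] * 7 + [3] * 3  # first n mod k folds get the extra
        tested = np.concatenate([te for _, te in idx])
        assert sorted(tested.tolist()) == list(range(23))

    def test_oracle_feature_agrees_with_loocv(self, rng):
        y = rng.normal(15, 3, 20)
        X = np.column_stack([y + rng.normal(0, 0.05, 20), rng.normal(size=20)])
        ph = toy_phenotypes(y)
        loo = run_loocv(X, ph)
        kf = run_repeated_kfold(X, ph, k=10, repeats=5, seed=2)
        assert kf.metrics["r"] == pytest.approx(loo.metrics["r"], abs=0.05)

    def test_k_larger_than_n_rejected(self, rng):
        y = rng.normal(15, 3, 6)
        with pytest.raises(ValueError, match="exceeds"):
            run_repeated_kfold(rng.uniform(0, 1, (6, 2)), toy_phenotypes(y), k=10)


class TestNoLeakage:
    def test_poisoned_test_rows_do_not_change_fits(self, rng):
        """Scaling parameters and model fits never see held-out rows:
        replacing them with NaN leaves every fitted parameter identical."""
        y = rng.normal(15, 3, 8)
        X = rng.uniform(0, 1, (8, 5))
        for i in range(8):
            train = np.delete(np.arange(8), i)
            test = np.array([i])
            clean, _ = fit_fold(X, y, train, test)
            poisoned_X = X.copy()
            poisoned_X[test] = np.nan
            # the poisoned copy may only be used for training bookkeeping
            model = rvr.fit_rvr(
                minmax_scale_fold(poisoned_X[train], X[test])[0], y[train])
            np.testing.assert_array_equal(model.sample_weights,
                                          clean.sample_weights)
            assert model.bias == clean.bias
            assert model.noise_variance == clean.noise_variance

    def test_kfold_poisoning_leaves_fits_unchanged(self, rng):
        y = rng.normal(15, 3, 12)
        X = rng.uniform(0, 1, (12, 4))
        for train, test in kfold_indices(12, 4, seed=3, repeat=0):
            clean, _ = fit_fold(X, y, train, test)
            poisoned = X.copy()
            poisoned[test] = np.nan
            tr, _ = minmax_scale_fold(poisoned[train], X[test])
            model = rvr.fit_rvr(tr, y[train])
            np.testing.assert_array_equal(model.sample_weights,
                                          clean.sample_weights)
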