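import numpy as np
import pytest
from scipy import stats

import setsig as sg
from setsig.centroid import auc, decision_values, fit_centroid
from setsig.validation import (
    SplitPlan,
    align_datasets,
    auc_variance_ci,
    bagged_fit_predict,
    default_feature_grid,
    external_validation,
    internal_validation,
    internal_bagged_auc,
    split_subsample,
)


def labelled_features(rng, p=40, n=60, shift=1.0, n_pos=15):
    y = np.array([1] * n_pos + [-1] * (n - n_pos))
    X = rng.normal(size=(p, n))
    X[: p // 4, y == 1] += shift  # informative first quarter
    return X, y


class TestSplitSubsample:
    def test_stratified_floor_arithmetic(self):
        y = np.array([1, 1, 1, -1, -1, -1])
        plan = SplitPlan(B=1, train_frac=2 / 3, seed=0)
        train, test = split_subsample(y, plan)[0]
        assert len(train) == 4 and len(test) == 2
        assert (y[train] == 1).sum() == 2 and (y[test] == 1).sum() == 1

    def test_partition_property(self):
        y = np.array([1] * 10 + [-1] * 30)
        for train, test in split_subsample(y, SplitPlan(B=5, seed=1)):
            assert sorted(np.concatenate([train, test])) == list(range(40))

    def test_b_splits_returned(self):
        y = np.array([1] * 5 + [-1] * 5)
        assert len(split_subsample(y, SplitPlan(B=25, seed=2))) == 25

    def test_seed_determinism(self):
        y = np.array([1] * 8 + [-1] * 12)
        a = split_subsample(y, SplitPlan(B=3, seed=7))
        b = split_subsample(y, SplitPlan(B=3, seed=7))
        c = split_subsample(y, SplitPlan(B=3, seed=8))
        assert all(np.array_equal(x[0], y_[0]) for x, y_ in zip(a, b))
        assert any(not np.array_equal(x[0], y_[0]) for x, y_ in zip(a, c))

    def test_tiny_class_errors_under_stratification(self):
        y = np.array([1, -1, -1, -1])
        with pytest.raises(ValueError, match="stratified"):
            split_subsample(y, SplitPlan(B=1, seed=0))


class TestBaggedFitPredict:
    def test_degenerate_full_train_equals_single_model(self, rng):
        X, y = labelled_features(rng)
        plan = SplitPlan(B=1, train_frac=0.999, seed=0)
        # train_frac→1 keeps all but one sample per class out of test
        bag = bagged_fit_predict(X, y, X, plan)
        train, _ = split_subsample(y, plan)[0]
        single = decision_values(fit_centroid(X[:, train], y[train]), X)
        assert np.allclose(bag, single, atol=1e-12)

    def test_duplicated_training_data_makes_bagging_trivial(self):
        # every subsample of duplicated identical blocks fits the same model
        block = np.array([[1.0, 2.0, -1.0, -2.0]])
        X = np.tile(block, 10)
        y = np.tile([1, 1, -1, -1], 10)
        plan = SplitPlan(B=5, train_frac=0.5, seed=3)
        # means of each class are identical in every subsample only in
        # expectation; use literally constant class values instead
        Xc = np.where(y == 1, 2.0, -2.0)[None, :]
        bag = bagged_fit_predict(Xc, y, Xc, plan)
        single = decision_values(fit_centroid(Xc, y), Xc)
        assert np.allclose(bag, single, atol=1e-12)

    def test_bad_top_k_errors(self, rng):
        X, y = labelled_features(rng)
        with pytest.raises(ValueError, match="top_k"):
            bagged_fit_predict(X, y, X, SplitPlan(B=1, seed=0), top_k=0)

    def test_bagging_reduces_prediction_mse(self, rng):
        # Breiman property on synthetic replicates: bagged predictions track
        # the large-sample decision values at least as well on average as a
        # single subsample model
        p, n = 30, 90
        truth_X, truth_y = labelled_features(rng, p=p, n=3000, n_pos=750)
        ref_model = fit_centroid(truth_X, truth_y)
        mse_single, mse_bag = [], []
        for rep in range(10):
            X, y = labelled_features(np.random.default_rng(rep), p=p, n=n, n_pos=22)
            target = decision_values(ref_model, X)
            plan = SplitPlan(B=25, seed=rep)
            bag = bagged_fit_predict(X, y, X, plan)
            train, _ = split_subsample(y, SplitPlan(B=1, seed=rep))[0]
            single = decision_values(fit_centroid(X[:, train], y[train]), X)
            # compare on the correlation-invariant scale
            mse_bag.append(np.mean((stats.zscore(bag) - stats.zscore(target)) ** 2))
            mse_single.append(np.mean((stats.zscore(single) - stats.zscore(target)) ** 2))
        assert np.mean(mse_bag) <= np.mean(mse_single) + 1e-9


class TestInternalValidation:
    def test_report_row_count_per_feature_grid(self, rng):
        X, y = labelled_features(rng)
        rep = internal_validation(X, y, SplitPlan(B=4, seed=0),
                                  feature_grid=[2, 8, 40])
        assert len(internal_bagged_auc(rep)) == 3

    def test_permuted_labels_near_half(self, rng):
        X, y = labelled_features(rng, shift=1.5)
        aucs = []
        for seed in range(6):
            perm = np.random.default_rng(seed).permutation(y.size)
            rep = internal_validation(X, y[perm], SplitPlan(B=10, seed=seed),
                                      feature_grid=[X.shape[0]])
            aucs.append(internal_bagged_auc(rep)["auc"].iloc[0])
        aucs = np.array(aucs)
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * max(se, 0.02)

    def test_separable_data_high_auc(self, rng):
        X, y = labelled_features(rng, shift=3.0)
        rep = internal_validation(X, y, SplitPlan(B=10, seed=1),
                                  feature_grid=[10])
        assert internal_bagged_auc(rep)["auc"].iloc[0] > 0.9


class TestExternalValidation:
    def make_datasets(self, d, rng, shift=2.0):
        out = []
        for i in range(d):
            X, y = labelled_features(np.random.default_rng(rng.integers(2**31)),
                                     shift=shift)
            out.append((f"ds{i}", X, y))
        return out

    def test_five_datasets_give_twenty_ordered_pairs(self, rng):
        datasets = self.make_datasets(5, rng)
        rep = external_validation(datasets, SplitPlan(B=2, seed=0),
                                  feature_grid=[10])
        pairs = rep.table[["train", "test"]].drop_duplicates()
        assert len(pairs) == 20

    def test_two_datasets_give_two_pairs(self, rng):
        rep = external_validation(self.make_datasets(2, rng),
                                  SplitPlan(B=2, seed=0), feature_grid=[10])
        assert len(rep.table[["train", "test"]].drop_duplicates()) == 2

    def test_identical_datasets_match_internal_auc(self, rng):
        X, y = labelled_features(rng, shift=2.0)
        rep_ext = external_validation([("a", X, y), ("b", X.copy(), y.copy())],
                                      SplitPlan(B=10, seed=0), feature_grid=[40])
        rep_int = internal_validation(X, y, SplitPlan(B=10, seed=0),
                                      feature_grid=[40])
        ext = rep_ext.table["auc"].mean()
        internal = internal_bagged_auc(rep_int)["auc"].iloc[0]
        assert ext == pytest.approx(internal, abs=0.1)

    def test_mismatched_feature_space_errors(self, rng):
        a = ("a", rng.normal(size=(10, 20)), np.array([1] * 5 + [-1] * 15))
        b = ("b", rng.normal(size=(11, 20)), np.array([1] * 5 + [-1] * 15))
        with pytest.raises(ValueError, match="feature space"):
            external_validation([a, b], SplitPlan(B=1, seed=0))


class TestAucVarianceCi:
    def test_constant_values(self):
        var, lo, hi = auc_variance_ci(np.full(5, 0.7))
        assert var == lo == hi == 0.0

    def test_two_value_quantile_example(self):
        # n=2, s²=1: CI = (1/χ²_{0.975,1}, 1/χ²_{0.025,1}) ≈ (0.199, 1018.3)
        vals = np.array([0.0, np.sqrt(2.0)])  # sample variance exactly 1
        var, lo, hi = auc_variance_ci(vals, alpha=0.05)
        assert var == pytest.approx(1.0)
        assert lo == pytest.approx(0.199, abs=5e-4)
        assert hi == pytest.approx(1018.3, rel=1e-3)

    def test_ci_contains_sample_variance(self, rng):
        for _ in range(20):
            vals = rng.normal(size=rng.integers(3, 30))
            var, lo, hi = auc_variance_ci(vals)
            assert lo <= var <= hi

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            auc_variance_ci(np.array([0.5]))


class TestAlignment:
    def test_common_features_in_first_dataset_order(self, small_data):
        datasets, _, _ = small_data
        ds0, ds1 = datasets[0], datasets[1].subset_features(range(100, 300))
        a, b = align_datasets([ds0, ds1])
        assert list(a.feature_ids) == list(b.feature_ids)
        assert len(a.feature_ids) == 200

    def test_empty_intersection_errors(self, small_data):
        datasets, _, _ = small_data
        ds0 = datasets[0].subset_features(range(0, 100))
        ds1 = datasets[1].subset_features(range(100, 200))
        with pytest.raises(ValueError, match="intersection"):
            align_datasets([ds0, ds1])


def test_default_feature_grid_powers_of_two():
    assert default_feature_grid(20) == [1, 2, 4, 8, 16, 20]
    assert default_feature_grid(16) == [1, 2, 4, 8, 16]
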