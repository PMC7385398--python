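import numpy as np
import pytest

import braindiff.mvpa as mv
from braindiff.mvpa import (
    FeatureMatrix,
    concat_modalities,
    cv_classify,
    make_feature_grid,
    make_folds,
    permutation_test,
    residualize_features,
    roc_auc,
    znorm_per_subject,
)


def gaussian_classes(rng, n_per_group, n_features, d=0.0, n_informative=None):
    """Synthetic feature matrix: males first, mean shift d on informative cols."""
    if n_informative is None:
        n_informative = n_features
    X = rng.standard_normal((2 * n_per_group, n_features))
    X[:n_per_group, :n_informative] += d
    y = np.array(["M"] * n_per_group + ["F"] * n_per_group)
    return FeatureMatrix(X), y


def pairwise_auc_oracle(values, is_male):
    """O(n^2) brute force: P(male value > female value), ties as 1/2."""
    wins = 0.0
    pos = values[is_male]
    neg = values[~is_male]
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


class TestResidualize:
    def test_orthogonal_covariate_only_demeans(self, rng):
        n = 30
        cov = rng.standard_normal(n)
        cov -= cov.mean()
        col = rng.standard_normal(n)
        col -= (col @ cov) / (cov @ cov) * cov  # orthogonal to centered covariate
        X = FeatureMatrix(col[:, None])
        out = residualize_features(X, cov)
        np.testing.assert_allclose(
            out.values[:, 0], col - col.mean(), atol=1e-10
        )

    def test_exact_linear_column_zeroed(self, rng):
        n = 25
        cov = rng.standard_normal((n, 2))
        col = 2.0 * cov[:, 0] - 0.5 * cov[:, 1] + 3.0
        out = residualize_features(FeatureMatrix(col[:, None]), cov)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 40
        cov = rng.standard_normal((n, 3))
        X = FeatureMatrix(rng.standard_normal((n, 6)))
        out = residualize_features(X, cov)
        D = np.column_stack([np.ones(n), cov])
        inner = np.abs(D.T @ out.values)
        bound = (
            1e-8
            * np.linalg.norm(D, axis=0)[:, None]
            * np.linalg.norm(out.values, axis=0)[None, :]
        )
        assert (inner <= bound + 1e-12).all()

    def test_rank_deficient_rejected(self, rng):
        cov = np.ones((10, 1))  # collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            residualize_features(FeatureMatrix(rng.standard_normal((10, 3))), cov)


class TestZnorm:
    def test_hand_computed_row(self):
        out = znorm_per_subject(FeatureMatrix(np.array([[1.0, 2.0, 3.0]])))
        np.testing.assert_allclose(
            out.values[0], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_standardized_row_unchanged(self):
        row = np.array([[-1.0, 0.0, 1.0]]) * np.sqrt(1.5)  # mean 0, pop SD 1
        out = znorm_per_subject(FeatureMatrix(row))
        np.testing.assert_allclose(out.values, row, atol=1e-12)

    def test_all_rows_standardized(self, rng):
        out = znorm_per_subject(FeatureMatrix(rng.standard_normal((7, 50)) * 4 + 2))
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=1), 1.0, atol=1e-10)

    def test_zero_variance_row_rejected(self):
        with pytest.raises(ValueError, match="zero feature variance"):
            znorm_per_subject(FeatureMatrix(np.ones((2, 4))))


class TestConcat:
    def test_combined_feature_count(self):
        parts = [
            FeatureMatrix(np.zeros((2, 67541)), modality="gmv"),
            FeatureMatrix(np.zeros((2, 67541)), modality="reho"),
            FeatureMatrix(np.zeros((2, 6670)), modality="fc"),
        ]
        out = concat_modalities(parts)
        assert out.n_features == 141752

    def test_single_part_identity(self, rng):
        p = FeatureMatrix(rng.standard_normal((3, 5)), modality="gmv")
        out = concat_modalities([p])
        np.testing.assert_array_equal(out.values, p.values)
        assert out.feature_ids == p.feature_ids

    def test_provenance_tags_round_trip(self, rng):
        a = FeatureMatrix(rng.standard_normal((3, 4)), modality="gmv")
        b = FeatureMatrix(rng.standard_normal((3, 2)), modality="fc")
        out = concat_modalities([a, b])
        assert out.feature_ids == [("gmv", j) for j in range(4)] + [
            ("fc", j) for j in range(2)
        ]

    def test_subject_mismatch_rejected(self, rng):
        a = FeatureMatrix(rng.standard_normal((3, 4)), subject_ids=["a", "b", "c"])
        b = FeatureMatrix(rng.standard_normal((3, 4)), subject_ids=["a", "c", "b"])
        with pytest.raises(ValueError, match="subject"):
            concat_modalities([a, b])


class TestMakeFolds:
    def test_printed_cohort_composition(self):
        folds = make_folds(135, 155, 10, seed=0)
        assert folds.per_fold_composition[:9] == [(13, 15)] * 9
        assert folds.per_fold_composition[9] == (18, 20)

    def test_exact_division(self):
        folds = make_folds(20, 20, 10, seed=1)
        assert folds.per_fold_composition == [(2, 2)] * 10

    @pytest.mark.parametrize("n_male,n_female,k", [(23, 31, 5), (17, 19, 4)])
    def test_partition_property(self, n_male, n_female, k):
        folds = make_folds(n_male, n_female, k, seed=3)
        comp = np.array(folds.per_fold_composition)
        assert comp[:, 0].sum() == n_male
        assert comp[:, 1].sum() == n_female
        assert len(folds.assignments) == n_male + n_female
        assert set(folds.assignments) == set(range(k))

    def test_deterministic(self):
        f1 = make_folds(30, 32, 6, seed=9)
        f2 = make_folds(30, 32, 6, seed=9)
        np.testing.assert_array_equal(f1.assignments, f2.assignments)

    def test_group_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 30, 10)


class TestFeatureGrid:
    @pytest.mark.parametrize(
        "step,total,expected_len",
        [(2000, 67541, 34), (100, 6670, 67), (2000, 141752, 71)],
    )
    def test_printed_grid_sizes(self, step, total, expected_len):
        grid = make_feature_grid(step, total)
        assert len(grid) == expected_len
        assert grid[-1] == total
        assert list(grid) == sorted(set(grid))

    def test_step_larger_than_total(self):
        assert make_feature_grid(100, 30) == (30,)

    def test_exact_multiple_no_duplicate(self):
        assert make_feature_grid(10, 30) == (10, 20, 30)


class TestCvClassify:
    def test_separable_classes_high_accuracy(self, rng):
        X, y = gaussian_classes(rng, 40, 50, d=4.0)
        folds = make_folds(40, 40, 5, seed=0)
        res = cv_classify(X, y, folds, make_feature_grid(10, 50))
        assert res.best_mean_accuracy >= 0.95
        assert res.auc[res.best_grid_point] > 0.95

    def test_shuffled_labels_chance_level(self, rng):
        X, y = gaussian_classes(rng, 40, 30, d=2.0)
        y = y[rng.permutation(len(y))]
        n_male = int((y[: 40] == "M").sum())
        # rebuild male-first ordering to match fold construction
        order = np.argsort(y != "M", kind="stable")
        X = FeatureMatrix(X.values[order])
        y = y[order]
        folds = make_folds(40, 40, 5, seed=1)
        res = cv_classify(X, y, folds, (30,))
        assert 0.35 <= res.mean_accuracy[0] <= 0.65

    def test_full_grid_equals_plain_cv(self, rng):
        from sklearn.svm import SVC

        X, y = gaussian_classes(rng, 15, 12, d=1.0)
        folds = make_folds(15, 15, 3, seed=2)
        res = cv_classify(X, y, folds, (12,))
        # oracle: plain CV without any selection
        male = y == "M"
        accs = []
        for f in range(3):
            tr, te = folds.train_indices(f), folds.test_indices(f)
            clf = SVC(kernel="linear", C=1.0).fit(X.values[tr], male[tr].astype(int))
            accs.append(((clf.decision_function(X.values[te]) > 0) == male[te]).mean())
        assert res.mean_accuracy[0] == pytest.approx(np.mean(accs), abs=1e-12)

    def test_fold_determinism(self, rng):
        X, y = gaussian_classes(rng, 12, 20, d=1.0)
        folds = make_folds(12, 12, 4, seed=5)
        r1 = cv_classify(X, y, folds, (5, 20))
        r2 = cv_classify(X, y, folds, (5, 20))
        np.testing.assert_array_equal(r1.decision_values, r2.decision_values)
        np.testing.assert_array_equal(r1.mean_accuracy, r2.mean_accuracy)

    def test_best_grid_point_maximizes_mean_accuracy(self, rng):
        X, y = gaussian_classes(rng, 20, 30, d=1.5, n_informative=5)
        folds = make_folds(20, 20, 4, seed=3)
        res = cv_classify(X, y, folds, (5, 15, 30))
        assert res.mean_accuracy[res.best_grid_point] == res.mean_accuracy.max()

    def test_selection_prefers_informative_features(self, rng):
        # with 5 informative of 60 features, accuracy at grid point 5
        # should not trail the full set by much (monotonicity sanity)
        diffs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X, y = gaussian_classes(r, 25, 60, d=1.2, n_informative=5)
            folds = make_folds(25, 25, 5, seed=seed)
            res = cv_classify(X, y, folds, (5, 60))
            diffs.append(res.mean_accuracy[0] - res.mean_accuracy[1])
        assert np.mean(diffs) > -0.05

    def test_no_test_leakage_instrumented(self, rng, monkeypatch):
        """Every SVM fit must see only training-set rows."""
        fit_sizes = []
        orig_fit = mv.SVC.fit

        def spy_fit(self, X, y, **kw):
            fit_sizes.append(len(X))
            return orig_fit(self, X, y, **kw)

        monkeypatch.setattr(mv.SVC, "fit", spy_fit)
        X, y = gaussian_classes(rng, 10, 8, d=1.0)
        folds = make_folds(10, 10, 4, seed=0)
        cv_classify(X, y, folds, (4, 8))
        train_sizes = {len(folds.train_indices(f)) for f in range(4)}
        assert fit_sizes and set(fit_sizes) <= train_sizes

    def test_degenerate_training_fold_rejected(self, rng):
        X, y = gaussian_classes(rng, 3, 5)
        # all males land in fold 0, so fold 0's training set is one-class
        folds = mv.FoldSpec(
            k=2,
            assignments=np.array([0, 0, 0, 1, 1, 1]),
            per_fold_composition=[(3, 0), (0, 3)],
        )
        with pytest.raises(ValueError, match="degenerate"):
            cv_classify(X, y, folds, (5,))

    def test_invalid_grid_rejected(self, rng):
        X, y = gaussian_classes(rng, 5, 5)
        folds = make_folds(5, 5, 2, seed=0)
        with pytest.raises(ValueError, match="grid"):
            cv_classify(X, y, folds, (10,))


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array(["M"] * 3 + ["F"] * 3)
        curve, auc = roc_auc(np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0]), y)
        assert auc == 1.0
        assert curve.iloc[0].tolist() == [0.0, 0.0]
        assert curve.iloc[-1].tolist() == [1.0, 1.0]

    def test_all_ties_half(self):
        y = np.array(["M", "M", "F", "F"])
        _, auc = roc_auc(np.zeros(4), y)
        assert auc == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = 20
        y = np.array(["M"] * 8 + ["F"] * 12)
        d = np.round(r.standard_normal(n), 1)  # rounding forces ties
        _, auc = roc_auc(d, y)
        assert auc == pytest.approx(pairwise_auc_oracle(d, y == "M"), abs=1e-12)

    def test_curve_monotone(self, rng):
        y = np.array(["M"] * 10 + ["F"] * 10)
        curve, _ = roc_auc(rng.standard_normal(20), y)
        assert (np.diff(curve["fpr"]) >= 0).all()
        assert (np.diff(curve["tpr"]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.array(["M"] * 4))


class TestPermutationTest:
    def test_actual_zero_gives_p_one(self, rng):
        X, y = gaussian_classes(rng, 8, 6)
        folds = make_folds(8, 8, 4, seed=0)
        null = permutation_test(X, y, folds, 6, 20, actual_accuracy=0.0, seed=1)
        assert null.p_value == 1.0

    def test_p_floored_at_one_over_n_perm(self, rng):
        X, y = gaussian_classes(rng, 8, 6, d=5.0)
        folds = make_folds(8, 8, 4, seed=0)
        null = permutation_test(X, y, folds, 6, 40, actual_accuracy=1.0, seed=1)
        assert null.p_value >= 1.0 / 40
        if (null.null_accuracies >= 1.0).sum() == 0:
            assert null.p_value == 1.0 / 40

    def test_null_centered_at_chance(self, rng):
        X, y = gaussian_classes(rng, 20, 10, d=0.0)
        folds = make_folds(20, 20, 4, seed=2)
        null = permutation_test(X, y, folds, 10, 60, actual_accuracy=0.9, seed=3)
        assert abs(null.null_accuracies.mean() - 0.5) < 0.06

    def test_bonferroni_factor_applied(self, rng):
        X, y = gaussian_classes(rng, 8, 6)
        folds = make_folds(8, 8, 4, seed=0)
        null = permutation_test(
            X, y, folds, 6, 20, actual_accuracy=0.0, seed=1, bonferroni_factor=34
        )
        assert null.p_bonferroni == 1.0
        assert null.bonferroni_factor == 34

    def test_deterministic_under_seed(self, rng):
        X, y = gaussian_classes(rng, 8, 6, d=1.0)
        folds = make_folds(8, 8, 4, seed=0)
        n1 = permutation_test(X, y, folds, 3, 15, 0.8, seed=4)
        n2 = permutation_test(X, y, folds, 3, 15, 0.8, seed=4)
        np.testing.assert_array_equal(n1.null_accuracies, n2.null_accuracies)
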