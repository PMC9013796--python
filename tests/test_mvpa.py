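"""LOOCV pattern classification/regression and permutation inference."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC, SVR

from ampdyn import (
    extract_features,
    loocv_classify,
    loocv_svr,
    permutation_test,
    regionwise_classify,
    regionwise_predict,
    roc_curve_auc,
)
from ampdyn.mvpa import FeatureMatrix


def separated_clouds(rng, n_per=10, d=6, gap=6.0):
    X = np.vstack(
        [rng.standard_normal((n_per, d)) + gap, rng.standard_normal((n_per, d))]
    )
    y = np.r_[np.ones(n_per), np.zeros(n_per)].astype(int)
    return X, y


class TestExtractFeatures:
    def test_shape_and_order(self, rng):
        maps = rng.standard_normal((10, 6, 5, 4))
        mask = np.zeros((6, 5, 4), dtype=bool)
        mask[1, 2, 3] = mask[0, 0, 0] = mask[5, 4, 3] = True
        fm = extract_features(maps, mask)
        assert fm.X.shape == (10, 3)
        # lexicographic voxel order
        np.testing.assert_array_equal(fm.coords, [[0, 0, 0], [1, 2, 3], [5, 4, 3]])
        np.testing.assert_array_equal(fm.X[:, 0], maps[:, 0, 0, 0])

    def test_single_voxel_mask(self, rng):
        maps = rng.standard_normal((7, 3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        fm = extract_features(maps, mask)
        np.testing.assert_array_equal(fm.X[:, 0], maps[:, 1, 1, 1])

    def test_subject_reorder_permutes_rows(self, rng):
        maps = rng.standard_normal((8, 4, 4, 2))
        mask = np.ones((4, 4, 2), dtype=bool)
        perm = rng.permutation(8)
        a = extract_features(maps, mask).X
        b = extract_features(maps[perm], mask).X
        np.testing.assert_array_equal(b, a[perm])

    def test_empty_mask_errors(self, rng):
        with pytest.raises(ValueError, match="empty"):
            extract_features(rng.standard_normal((4, 2, 2, 2)), np.zeros((2, 2, 2), bool))

    def test_region_label_selection(self, rng):
        maps = rng.standard_normal((5, 4, 4, 2))
        atlas = np.zeros((4, 4, 2), dtype=int)
        atlas[:2] = 1
        atlas[2:] = 2
        fm = extract_features(maps, atlas, region_label=2)
        assert fm.X.shape == (5, 16)


class TestLOOCVClassify:
    def test_separable_data_classified_perfectly(self, rng):
        X, y = separated_clouds(rng)
        cv, sens = loocv_classify(X, y)
        assert cv.mean_accuracy_pct == 100.0
        assert cv.auc == 1.0
        assert set(np.unique(cv.fold_accuracies)) <= {0.0, 100.0}

    def test_matches_scikit_learn_fold_loop(self, rng):
        # oracle: brute-force LOOCV with sklearn's libsvm, fold by fold
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((12, 8))
            y = np.r_[np.ones(6), np.zeros(6)].astype(int)
            X[y == 1] += 1.0
            cv, _ = loocv_classify(X, y)
            correct = 0
            for i in range(12):
                tr = np.arange(12) != i
                clf = SVC(kernel="linear", C=1.0).fit(X[tr], y[tr])
                dec = clf.decision_function(X[i][None])[0]
                pred = 1 if dec >= 0 else 0
                correct += pred == y[i]
            assert cv.mean_accuracy_pct == pytest.approx(correct / 12 * 100)

    def test_duplicated_feature_columns_leave_predictions_unchanged(self, rng):
        X, y = separated_clouds(rng, gap=4.0)
        cv1, _ = loocv_classify(X, y)
        cv2, _ = loocv_classify(np.hstack([X, X]), y)
        np.testing.assert_array_equal(cv1.predictions, cv2.predictions)

    def test_single_class_training_fold_errors(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="class"):
            loocv_classify(X, y)

    def test_consistency_mask_shrinks_with_more_folds(self, rng):
        X = rng.standard_normal((14, 10))
        y = np.r_[np.ones(7), np.zeros(7)].astype(int)
        X[y == 1, :3] += 1.5
        _, sens = loocv_classify(X, y)
        prev = sens.consistency_over_folds(2)
        for k in range(3, 15):
            cur = sens.consistency_over_folds(k)
            assert not np.any(cur & ~prev)  # cur is a subset of prev
            prev = cur
        np.testing.assert_array_equal(sens.consistency_over_folds(14), sens.consistency_mask)


class TestROC:
    def test_perfect_separation(self):
        dec = np.r_[np.ones(5), -np.ones(5)]
        y = np.r_[np.ones(5), np.zeros(5)]
        pts, auc = roc_curve_auc(dec, y)
        assert auc == 1.0
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]

    def test_negation_symmetry(self, rng):
        dec = rng.standard_normal(40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        _, auc = roc_curve_auc(dec, y)
        _, auc_neg = roc_curve_auc(-dec, y)
        assert auc_neg == pytest.approx(1.0 - auc, abs=1e-12)

    def test_matches_sklearn_with_ties(self, rng):
        dec = np.round(rng.standard_normal(60), 1)  # force ties
        y = (rng.random(60) < 0.5).astype(int)
        y[:2] = [0, 1]
        _, auc = roc_curve_auc(dec, y)
        assert auc == pytest.approx(roc_auc_score(y, dec), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_curve_auc(np.arange(4.0), np.ones(4))


class TestPermutationTest:
    def test_observed_below_all_null_gives_p_one(self, rng):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        X = rng.standard_normal((20, 4))
        ref = y.copy()
        stat = lambda Xa, yy: 0.0 if np.array_equal(yy, ref) else 1.0
        null = permutation_test(X, y, statistic_fn=stat, n_perm=100, seed=0)
        assert null.p_value == 1.0

    def test_observed_above_all_null_gives_floor(self, rng):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        X = rng.standard_normal((20, 4))
        ref = y.copy()
        stat = lambda Xa, yy: 1.0 if np.array_equal(yy, ref) else 0.0
        null = permutation_test(X, y, statistic_fn=stat, n_perm=100, seed=0)
        assert null.p_value == pytest.approx(1.0 / 100)

    def test_strong_effect_detected(self, rng):
        X, y = separated_clouds(rng, gap=3.0)
        null = permutation_test(X, y, n_perm=200, seed=3)
        assert null.observed == 1.0
        assert null.p_value <= 0.01

    def test_null_reproducible_with_seed(self, rng):
        X, y = separated_clouds(rng, gap=0.0)
        a = permutation_test(X, y, n_perm=100, seed=11)
        b = permutation_test(X, y, n_perm=100, seed=11)
        np.testing.assert_array_equal(a.null_values, b.null_values)


class TestSVR:
    def test_recovers_noiseless_linear_target(self, rng):
        X = rng.standard_normal((30, 2))
        target = 2.0 * X[:, 0] - 1.0 * X[:, 1]
        cv = loocv_svr(X, target)
        assert cv.pearson_r >= 0.95
        assert cv.rmse == pytest.approx(
            np.sqrt(np.mean((cv.predictions - target) ** 2)), abs=1e-12
        )

    def test_matches_scikit_learn_fold_loop(self, rng):
        X = rng.standard_normal((12, 5))
        target = X @ rng.standard_normal(5) * 0.5 + 0.3 * rng.standard_normal(12)
        cv = loocv_svr(X, target)
        preds = []
        for i in range(12):
            tr = np.arange(12) != i
            m = SVR(kernel="linear", C=1.0, epsilon=0.1).fit(X[tr], target[tr])
            preds.append(m.predict(X[i][None])[0])
        np.testing.assert_allclose(cv.predictions, preds, atol=5e-3)

    def test_null_target_mean_r_near_zero(self, rng):
        X = rng.standard_normal((20, 10))
        target = rng.standard_normal(20)
        null = permutation_test(X, target, statistic="r", n_perm=200, seed=5)
        assert abs(null.null_values.mean()) < 0.05

    def test_constant_target_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            loocv_svr(rng.standard_normal((8, 3)), np.ones(8))


def block_atlas(grid=(6, 6, 4), n_regions=4):
    atlas = np.zeros(grid, dtype=int)
    xs = np.array_split(np.arange(grid[0]), n_regions)
    for k, sl in enumerate(xs):
        atlas[sl] = k + 1
    return atlas


class TestRegionwise:
    def test_single_region_corrected_p_equals_plain_permutation_p(self, rng):
        maps = rng.standard_normal((16, 6, 6, 4))
        y = np.r_[np.ones(8), np.zeros(8)].astype(int)
        maps[y == 1, :3] += 1.0
        atlas = np.where(np.ones((6, 6, 4), bool), 1, 0)
        rt = regionwise_classify(maps, y, atlas, n_perm=100, seed=9)
        fm = extract_features(maps, atlas.astype(bool))
        plain = permutation_test(fm, y, n_perm=100, seed=9)
        assert rt.loc[0, "p_fwe"] == pytest.approx(plain.p_value)

    def test_corrected_p_monotone_vs_own_region_null(self, rng):
        maps = rng.standard_normal((16, 6, 6, 4))
        y = np.r_[np.ones(8), np.zeros(8)].astype(int)
        maps[y == 1, :2] += 1.2
        atlas = block_atlas()
        rt = regionwise_classify(maps, y, atlas, n_perm=100, seed=2)
        for _, row in rt.iterrows():
            fm = extract_features(maps, atlas, region_label=int(row["region"]))
            plain = permutation_test(fm, y, n_perm=100, seed=2)
            assert row["p_fwe"] >= plain.p_value - 1e-12

    def test_planted_region_flagged(self, rng):
        maps = rng.standard_normal((20, 6, 6, 4))
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        atlas = block_atlas()
        pat = maps[y == 1]
        pat[:, atlas == 3] += 2.0
        maps[y == 1] = pat
        rt = regionwise_classify(maps, y, atlas, n_perm=100, seed=4)
        assert bool(rt.loc[rt["region"] == 3, "significant"].iloc[0])

    def test_regionwise_predict_flags_prognostic_region(self, rng):
        n = 24
        maps = rng.standard_normal((n, 6, 6, 4))
        atlas = block_atlas()
        s = rng.standard_normal(n)
        maps[:, atlas == 2] += 1.5 * s[:, None]
        target = s + 0.2 * rng.standard_normal(n)
        rt = regionwise_predict(maps, target, atlas, n_perm=100, seed=6)
        assert bool(rt.loc[rt["region"] == 2, "significant"].iloc[0])
        assert rt["p_fwe"].min() >= 1.0 / 100
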