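"""Metrics, preprocessing, and the nested-CV elastic-net benchmark."""

import numpy as np
import pytest

from morphorep.classify import (CVConfig, FeatureMatrix, FeatureTransform,
                                combine_representations, fit_alternative,
                                fit_binary, fit_multiclass, metric,
                                preprocess_features)

FAST = CVConfig(n_repeats=1)


def gaussian_pair(rng, n=20, p=5, separation=6.0):
    """Two gaussian clusters separated along the first feature."""
    Xa = rng.normal(0, 1, (n, p))
    Xb = rng.normal(0, 1, (n, p))
    Xb[:, 0] += separation
    X = np.vstack([Xa, Xb])
    labels = np.array(["a"] * n + ["b"] * n)
    return FeatureMatrix(X, labels, "test", kind="none")


class TestMetrics:
    def test_constant_half_probability_gives_ln2(self):
        y = np.array(["a", "b"] * 10)
        prob = np.full((20, 2), 0.5)
        assert metric("log_loss", y, prob) == pytest.approx(np.log(2), rel=1e-12)

    def test_uniform_multiclass_gives_lnk(self):
        for k in (11, 7, 6):
            y = np.repeat([f"c{i}" for i in range(k)], 3)
            prob = np.full((len(y), k), 1.0 / k)
            assert metric("log_loss", y, prob,
                          classes=np.unique(y)) == pytest.approx(np.log(k))

    def test_perfect_prediction(self):
        y = np.array(["a", "b", "a", "b"])
        prob = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        assert metric("log_loss", y, prob) == pytest.approx(0.0, abs=1e-12)
        assert metric("accuracy", y, y) == 1.0
        assert metric("macro_f1", y, y) == 1.0
        assert metric("mcc", y, y) == 1.0

    def test_mcc_from_confusion_table(self):
        # TP=40, TN=30, FP=10, FN=20:
        # (40*30 - 10*20) / sqrt(50 * 60 * 40 * 50) = 1000 / sqrt(6e6)
        y_true = np.array([1] * 60 + [0] * 40)
        y_pred = np.array([1] * 40 + [0] * 20 + [1] * 10 + [0] * 30)
        expected = 1000 / np.sqrt(50 * 60 * 40 * 50)
        assert metric("mcc", y_true, y_pred) == pytest.approx(expected, rel=1e-9)

    def test_mcc_single_class_truth_is_zero(self):
        with pytest.warns(UserWarning, match="MCC"):
            assert metric("mcc", np.array(["a", "a"]), np.array(["a", "b"])) == 0.0


class TestPreprocessing:
    def test_rank_one_training_data_keeps_one_pc(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        X = np.outer(rng.normal(size=30), base)
        tf = FeatureTransform("pca").fit(X)
        assert tf.n_components == 1

    def test_pc1_has_unit_sd_after_scaling(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 8)) * np.arange(1, 9)
        tf = FeatureTransform("pca").fit(X)
        Z = tf.transform(X)
        assert Z[:, 0].std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_test_rows_use_train_moments(self):
        rng = np.random.default_rng(2)
        train = FeatureMatrix(rng.normal(2, 1, (30, 6)), np.array(["a"] * 30),
                              kind="pca")
        test = FeatureMatrix(train.X.mean(0, keepdims=True), np.array(["a"]),
                             kind="pca")
        _, te = preprocess_features(train, test)
        assert np.allclose(te.X, 0, atol=1e-9)

    def test_zscore_route(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5, 3, (50, 4))
        tf = FeatureTransform("zscore").fit(X)
        Z = tf.transform(X)
        assert np.allclose(Z.mean(0), 0, atol=1e-9)
        assert np.allclose(Z.std(0, ddof=1), 1, rtol=1e-9)

    def test_zero_variance_train_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            FeatureTransform("pca").fit(np.ones((10, 3)))

    def test_no_leakage_from_test_rows(self):
        # permuting test rows must not change the fitted transform's output
        rng = np.random.default_rng(4)
        train = FeatureMatrix(rng.normal(size=(30, 5)), np.array(["a"] * 30),
                              kind="pca")
        test_X = rng.normal(size=(10, 5))
        t1 = preprocess_features(train, FeatureMatrix(
            test_X, np.array(["a"] * 10), kind="pca"))[1]
        perm = rng.permutation(10)
        t2 = preprocess_features(train, FeatureMatrix(
            test_X[perm], np.array(["a"] * 10), kind="pca"))[1]
        assert np.allclose(t1.X[perm], t2.X)

    def test_combine_representations(self):
        rng = np.random.default_rng(5)
        labels = np.array(["a", "b"] * 5)
        r1 = FeatureMatrix(rng.normal(size=(10, 3)), labels, "r1", kind="none")
        r2 = FeatureMatrix(rng.normal(size=(10, 4)), labels, "r2", kind="none")
        combo = combine_representations([r1, r2])
        assert combo.X.shape == (10, 7)
        doubled = combine_representations([r1, r1])
        assert doubled.X.shape == (10, 6)
        with pytest.raises(ValueError, match="different rows"):
            combine_representations([r1, FeatureMatrix(
                rng.normal(size=(10, 2)), labels[::-1], "r3", kind="none")])


class TestNestedCV:
    def test_separated_clusters_near_zero_loss(self):
        fm = gaussian_pair(np.random.default_rng(10), n=20, separation=8.0)
        res = fit_binary(fm, ("a", "b"), FAST)
        assert res.log_loss < 0.05
        assert res.mean("accuracy") == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(11)
        fm = gaussian_pair(rng, n=20, separation=0.0)  # no signal at all
        res = fit_binary(fm, ("a", "b"), FAST)
        assert abs(res.log_loss - np.log(2)) < 0.12

    def test_duplicating_samples_keeps_metrics(self):
        rng = np.random.default_rng(12)
        fm = gaussian_pair(rng, n=12, separation=6.0)
        dup = FeatureMatrix(np.vstack([fm.X, fm.X]),
                            np.concatenate([fm.labels, fm.labels]),
                            kind="none")
        r1 = fit_binary(fm, ("a", "b"), FAST)
        r2 = fit_binary(dup, ("a", "b"), FAST)
        assert abs(r1.log_loss - r2.log_loss) < 0.05
        assert abs(r1.mean("accuracy") - r2.mean("accuracy")) < 0.05

    def test_fold_assignment_deterministic(self):
        from sklearn.model_selection import RepeatedStratifiedKFold
        y = np.array(["a", "b"] * 10)
        X = np.zeros((20, 2))
        folds1 = [te for _, te in RepeatedStratifiedKFold(
            n_splits=5, n_repeats=2, random_state=17).split(X, y)]
        folds2 = [te for _, te in RepeatedStratifiedKFold(
            n_splits=5, n_repeats=2, random_state=17).split(X, y)]
        for a, b in zip(folds1, folds2):
            assert np.array_equal(a, b)

    def test_too_small_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="stratified"):
            fit_binary(FeatureMatrix(X, labels, kind="none"), ("a", "b"),
                       CVConfig())

    def test_multiclass_separated_and_uninformative(self):
        rng = np.random.default_rng(13)
        n, p = 15, 4
        X = np.vstack([rng.normal(0, 1, (n, p)),
                       rng.normal(8, 1, (n, p)),
                       rng.normal(-8, 1, (n, p))])
        labels = np.repeat(["a", "b", "c"], n)
        good = fit_multiclass(FeatureMatrix(X, labels, kind="none"), FAST)
        assert good.log_loss < 0.1
        noise = FeatureMatrix(rng.normal(size=X.shape), labels, kind="none")
        res = fit_multiclass(noise, FAST)
        assert abs(res.log_loss - np.log(3)) < 0.2


class TestAlternativeSchemes:
    def test_knn_separated_clusters(self):
        fm = gaussian_pair(np.random.default_rng(20), n=10, separation=10.0)
        res = fit_alternative(fm, ("a", "b"), "knn3", FAST)
        assert res.mean("accuracy") == pytest.approx(1.0)
        assert "log_loss" not in res.fold_metrics.columns

    def test_tree_deterministic(self):
        fm = gaussian_pair(np.random.default_rng(21), n=10, separation=2.0)
        r1 = fit_alternative(fm, ("a", "b"), "tree", FAST)
        r2 = fit_alternative(fm, ("a", "b"), "tree", FAST)
        assert np.allclose(r1.fold_metrics, r2.fold_metrics)

    def test_chance_accuracy_on_noise(self):
        fm = gaussian_pair(np.random.default_rng(22), n=20, separation=0.0)
        res = fit_alternative(fm, ("a", "b"), "knn3", FAST)
        assert abs(res.mean("accuracy") - 0.5) < 0.25
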