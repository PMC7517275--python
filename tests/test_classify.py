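"""Native classifiers: hand-derived decisions, oracle equivalence, protocol."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drstissue.classify import (
    cart_fit,
    cart_predict,
    knn_fit,
    knn_predict,
    lda_fit,
    lda_predict,
    make_classifier,
    make_split,
    nb_fit,
    nb_log_posterior,
    nb_predict,
    qda_fit,
    qda_log_discriminants,
    qda_predict,
    repeated_evaluation,
)
from drstissue.classify import lda_discriminants


def _blobs(rng, n_per=30, d=3, sep=6.0, classes=("fat", "skin", "nerve")):
    X, y = [], []
    for i, c in enumerate(classes):
        X.append(rng.normal(i * sep, 1.0, (n_per, d)))
        y += [c] * n_per
    return np.vstack(X), np.array(y)


class TestLDA:
    def test_1d_midpoint_boundary(self):
        X = np.array([[0.0], [1.0], [3.0], [4.0]])
        y = np.array(["fat", "fat", "skin", "skin"])
        model = lda_fit(X, y)
        assert lda_predict(model, [[1.9]])[0] == "fat"
        assert lda_predict(model, [[2.1]])[0] == "skin"
        # discriminants cross exactly at the midpoint x = 2
        d = lda_discriminants(model, [[2.0]])[0]
        assert d[0] == pytest.approx(d[1], abs=1e-9)

    def test_identity_covariance_is_nearest_mean(self, rng):
        X, y = _blobs(rng, n_per=50, d=2)
        model = lda_fit(X, y)
        means = {c: X[y == c].mean(axis=0) for c in np.unique(y)}
        queries = rng.normal(5, 4, (30, 2))
        pred = lda_predict(model, queries)
        for q, p in zip(queries, pred):
            nearest = min(means, key=lambda c: np.linalg.norm(q - means[c]))
            assert p == nearest

    def test_duplicating_rows_leaves_model_unchanged(self, rng):
        X, y = _blobs(rng)
        a = lda_fit(X, y)
        b = lda_fit(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(a.weights, b.weights, rtol=1e-8)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(np.zeros((3, 1)), np.array(["fat", "fat", "skin"]))

    def test_agrees_with_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = _blobs(rng, n_per=40, sep=2.0)
        ours = lda_predict(lda_fit(X, y), X)
        ref = (sklearn.LinearDiscriminantAnalysis(solver="lsqr")
               .fit(X, y).predict(X))
        assert np.mean(ours == ref) > 0.98


class TestQDA:
    def test_equal_covariances_match_lda(self, rng):
        X, y = _blobs(rng, n_per=200, d=2, sep=3.0)
        lda_pred = lda_predict(lda_fit(X, y), X)
        qda_pred = qda_predict(qda_fit(X, y), X)
        assert np.mean(lda_pred == qda_pred) > 0.97

    def test_tight_class_wins_near_shared_mean(self):
        X = np.array([[-1.0], [0.0], [1.0], [-15.0], [0.0], [15.0]])
        y = np.array(["fat"] * 3 + ["skin"] * 3)
        assert qda_predict(qda_fit(X, y), [[0.1]])[0] == "fat"

    def test_point_at_tight_class_mean(self, rng):
        X = np.vstack([rng.normal(0, 0.01, (20, 2)), rng.normal(5, 3, (20, 2))])
        y = np.array(["fat"] * 20 + ["skin"] * 20)
        assert qda_predict(qda_fit(X, y), [X[:20].mean(axis=0)])[0] == "fat"

    def test_log_discriminants_match_multivariate_normal(self, rng):
        X, y = _blobs(rng, n_per=10, d=2)
        model = qda_fit(X, y)
        q = rng.normal(0, 3, (5, 2))
        ours = qda_log_discriminants(model, q)
        for i, c in enumerate(model.classes):
            # our discriminant drops the class-independent -(d/2) ln(2 pi)
            ref = (np.log(model.priors[i])
                   + stats.multivariate_normal(model.means[i],
                                               model.covariances[i]).logpdf(q)
                   + 0.5 * 2 * np.log(2 * np.pi))
            np.testing.assert_allclose(ours[:, i], ref, rtol=1e-9)


class TestNaiveBayes:
    def test_well_separated_1d(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["fat", "fat", "skin", "skin"])
        assert nb_predict(nb_fit(X, y), [[0.4]])[0] == "fat"

    def test_duplicated_feature_keeps_decision(self, rng):
        X, y = _blobs(rng, d=2, sep=2.5)
        single = nb_predict(nb_fit(X, y), X)
        doubled = nb_predict(nb_fit(np.hstack([X, X]), y), np.hstack([X, X]))
        np.testing.assert_array_equal(single, doubled)

    def test_log_posterior_matches_product_of_gaussians(self, rng):
        X, y = _blobs(rng, n_per=8, d=3)
        model = nb_fit(X, y)
        q = rng.normal(0, 2, (4, 3))
        ours = nb_log_posterior(model, q)
        for i in range(len(model.classes)):
            ref = np.log(model.priors[i]) + stats.norm(
                model.means[i], np.sqrt(model.variances[i])
            ).logpdf(q).sum(axis=1)
            np.testing.assert_allclose(ours[:, i], ref, rtol=1e-9)

    def test_agrees_with_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.naive_bayes")
        X, y = _blobs(rng, n_per=30, sep=2.0)
        ours = nb_predict(nb_fit(X, y), X)
        ref = sklearn.GaussianNB(var_smoothing=0.0).fit(X, y).predict(X)
        assert np.mean(ours == ref) > 0.98


class TestKNN:
    def test_query_on_training_point(self, rng):
        X, y = _blobs(rng)
        model = knn_fit(X, y, k=1)
        np.testing.assert_array_equal(knn_predict(model, X), y)

    def test_majority_vote(self):
        X = np.array([[0.0], [0.2], [1.0]])
        y = np.array(["fat", "fat", "skin"])
        assert knn_predict(knn_fit(X, y, k=3), [[0.1]])[0] == "fat"

    def test_scale_invariance_of_decisions(self, rng):
        X, y = _blobs(rng, d=2)
        q = rng.normal(3, 3, (20, 2))
        a = knn_predict(knn_fit(X, y, k=5), q)
        b = knn_predict(knn_fit(2 * X, y, k=5), 2 * q)
        np.testing.assert_array_equal(a, b)

    def test_tie_broken_by_mean_distance(self):
        # two neighbors per class at k=4; skin pair is closer
        X = np.array([[-3.0], [-2.0], [1.0], [1.5]])
        y = np.array(["fat", "fat", "skin", "skin"])
        assert knn_predict(knn_fit(X, y, k=4), [[0.0]])[0] == "skin"

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            knn_fit(np.zeros((3, 1)), np.array(["a", "b", "c"]), k=4)


class TestCART:
    def test_1d_separable_single_split(self):
        X = np.array([[0.0], [1.0], [3.0], [4.0]])
        y = np.array(["fat", "fat", "skin", "skin"])
        model = cart_fit(X, y, min_leaf=1)
        assert 1.0 < model.root.threshold < 3.0
        assert model.root.left.is_leaf and model.root.right.is_leaf
        np.testing.assert_array_equal(cart_predict(model, X), y)

    def test_pure_input_depth_zero(self):
        model = cart_fit(np.arange(6.0).reshape(-1, 1), np.array(["fat"] * 6))
        assert model.root.is_leaf
        assert cart_predict(model, [[100.0]])[0] == "fat"

    def test_training_accuracy_on_separable_blobs(self, rng):
        X, y = _blobs(rng, n_per=40, d=2)
        model = cart_fit(X, y, min_leaf=1)
        assert np.mean(cart_predict(model, X) == y) == 1.0

    def test_chi2_criterion_also_separates(self, rng):
        X, y = _blobs(rng, n_per=30, d=2)
        model = cart_fit(X, y, min_leaf=1, criterion="chi2")
        assert np.mean(cart_predict(model, X) == y) > 0.95

    def test_agrees_with_sklearn_on_clean_data(self, rng):
        sklearn = pytest.importorskip("sklearn.tree")
        X, y = _blobs(rng, n_per=40, d=3)
        ours = cart_predict(cart_fit(X, y, min_leaf=5), X)
        ref = (sklearn.DecisionTreeClassifier(min_samples_leaf=5, random_state=0)
               .fit(X, y).predict(X))
        assert np.mean(ours == ref) > 0.95


class TestTranslationInvariance:
    @pytest.mark.parametrize("name,params", [
        ("lda", {}), ("qda", {}), ("knn", {"k": 5}), ("cart", {"min_leaf": 2}),
    ])
    def test_constant_offset_does_not_change_decisions(self, rng, name, params):
        X, y = _blobs(rng, d=2, sep=3.0)
        q = rng.normal(3, 3, (25, 2))
        shift = np.array([100.0, -50.0])
        a = make_classifier(name, params).fit(X, y).predict(q)
        b = make_classifier(name, params).fit(X + shift, y).predict(q + shift)
        np.testing.assert_array_equal(a, b)


class TestSplit:
    def _labels(self, n_per=100):
        return np.repeat(["fat", "skin", "nerve", "bone", "muscle"], n_per)

    def test_stratified_counts(self):
        labels = self._labels()
        plan = make_split(labels, train_fraction=0.2, seed=3)
        train_labels = labels[plan.train_indices]
        for c in np.unique(labels):
            assert (train_labels == c).sum() == 20

    def test_deterministic_per_seed(self):
        labels = self._labels()
        a = make_split(labels, seed=5)
        b = make_split(labels, seed=5)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    def test_disjoint_covering(self):
        labels = self._labels(20)
        plan = make_split(labels, seed=1)
        combined = np.sort(np.concatenate([plan.train_indices, plan.test_indices]))
        np.testing.assert_array_equal(combined, np.arange(labels.size))

    def test_sample_grouping_respected(self, small_dataset):
        plan = make_split(small_dataset.labels, small_dataset.meta,
                          train_fraction=0.5, unit="sample", seed=2)
        samples = small_dataset.meta["sample_id"].to_numpy()
        assert not set(samples[plan.train_indices]) & set(samples[plan.test_indices])

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            make_split(self._labels(), train_fraction=1.5)


class TestRepeatedEvaluation:
    def test_separated_classes_perfect_and_stable(self, rng):
        X, y = _blobs(rng, n_per=50, sep=30.0)
        res = repeated_evaluation(X, y, "lda", n_repeats=4, seed=0)
        assert res["mean_accuracy"] == 1.0
        assert res["sd_accuracy"] == 0.0

    def test_shuffled_labels_hit_chance_level(self, rng):
        X = rng.normal(0, 1, (1000, 3))
        y = rng.permutation(np.repeat(["fat", "skin", "nerve", "bone", "muscle"], 200))
        res = repeated_evaluation(X, y, "lda", n_repeats=5, seed=0)
        se = res["sd_accuracy"] / np.sqrt(5)
        assert abs(res["mean_accuracy"] - 0.2) < max(3 * se, 0.05)

    def test_seeded_reproducibility(self, rng):
        X, y = _blobs(rng)
        a = repeated_evaluation(X, y, "knn", n_repeats=3, seed=9)
        b = repeated_evaluation(X, y, "knn", n_repeats=3, seed=9)
        assert a["mean_accuracy"] == b["mean_accuracy"]
        assert a["sd_accuracy"] == b["sd_accuracy"]
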