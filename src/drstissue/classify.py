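"""Native multiclass classifiers and the train/test evaluation protocol.

Five classifiers are implemented from their definitions:

* LDA — Gaussian classes with a pooled covariance; the discriminant is
  linear, ``y_k(x) = w_k^T x + w_k0`` with ``w_k = S^-1 mu_k`` and
  ``w_k0 = -1/2 mu_k^T S^-1 mu_k + ln pi_k``.
* QDA — per-class covariances, quadratic log-discriminants.
* Gaussian Naive Bayes — per-feature class-conditional normals under the
  independence assumption.
* k-nearest neighbors — majority vote among the k Euclidean-nearest
  training points (class posterior K_k / K); ties break by smaller mean
  neighbor distance, then class order.
* CART — greedy binary tree on axis-aligned thresholds minimizing Gini
  impurity (an optional chi-square criterion maximizes the one-way test
  statistic of the split).

Covariances are ridge-regularized (eps = 1e-6 x mean diagonal) because
small training fractions of high-dimensional scores can be near-singular.

The split protocol uses one fifth of the data for training and the rest
for testing, stratified by class, either per spectrum or grouped by
physical sample; ``repeated_evaluation`` reports mean accuracy +/- sample
SD over R independent splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import CLASS_ORDER

__all__ = [
    "LDAModel",
    "QDAModel",
    "NBModel",
    "KNNModel",
    "CARTModel",
    "SplitPlan",
    "lda_fit",
    "lda_predict",
    "qda_fit",
    "qda_predict",
    "nb_fit",
    "nb_predict",
    "knn_fit",
    "knn_predict",
    "cart_fit",
    "cart_predict",
    "make_classifier",
    "make_split",
    "repeated_evaluation",
]

_RIDGE = 1e-6


def _class_order(labels: np.ndarray) -> list[str]:
    present = set(np.unique(labels).tolist())
    ordered = [c for c in CLASS_ORDER if c in present]
    extras = sorted(present - set(CLASS_ORDER))
    return ordered + extras


def _check_fit_inputs(X: np.ndarray, labels: np.ndarray, min_per_class: int = 2):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = _class_order(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (labels == c).sum() < min_per_class:
            raise ValueError(f"class {c!r} has fewer than {min_per_class} samples")
    return X, labels, classes


# ---------------------------------------------------------------------------
# discriminant classifiers


@dataclass
class LDAModel:
    classes: list[str]
    weights: np.ndarray      # (K, d): w_k
    biases: np.ndarray       # (K,): w_k0
    pooled_cov: np.ndarray
    priors: np.ndarray


def lda_fit(X, labels, priors: np.ndarray | None = None) -> LDAModel:
    X, labels, classes = _check_fit_inputs(X, labels)
    n, d = X.shape
    k = len(classes)
    if priors is None:
        priors = np.array([(labels == c).mean() for c in classes])
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()

    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    pooled = np.zeros((d, d))
    for i, c in enumerate(classes):
        sub = X[labels == c] - means[i]
        pooled += sub.T @ sub
    # MLE (1/n) normalization: invariant to replicating the training set;
    # decisions are unaffected by the overall covariance scale
    pooled /= n
    pooled = pooled + _RIDGE * max(np.mean(np.diag(pooled)), 1e-12) * np.eye(d)
    inv = np.linalg.inv(pooled)
    weights = means @ inv
    biases = -0.5 * np.einsum("kd,kd->k", weights, means) + np.log(priors)
    return LDAModel(classes, weights, biases, pooled, priors)


def lda_discriminants(model: LDAModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X @ model.weights.T + model.biases


def lda_predict(model: LDAModel, X) -> np.ndarray:
    scores = lda_discriminants(model, X)
    return np.array([model.classes[i] for i in np.argmax(scores, axis=1)])


@dataclass
class QDAModel:
    classes: list[str]
    means: np.ndarray         # (K, d)
    covariances: np.ndarray   # (K, d, d), ridge-regularized
    priors: np.ndarray


def qda_fit(X, labels) -> QDAModel:
    X, labels, classes = _check_fit_inputs(X, labels)
    d = X.shape[1]
    means, covs, priors = [], [], []
    for c in classes:
        sub = X[labels == c]
        mu = sub.mean(axis=0)
        centered = sub - mu
        cov = centered.T @ centered / max(len(sub) - 1, 1)
        ridge = _RIDGE * max(np.mean(np.diag(cov)), 1e-12)
        covs.append(cov + ridge * np.eye(d))
        means.append(mu)
        priors.append(len(sub))
    priors = np.array(priors, dtype=float)
    return QDAModel(classes, np.vstack(means), np.stack(covs), priors / priors.sum())


def qda_log_discriminants(model: QDAModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], len(model.classes)))
    for i in range(len(model.classes)):
        cov = model.covariances[i]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("class covariance not positive definite")
        diff = X - model.means[i]
        maha = np.einsum("nd,nd->n", diff @ np.linalg.inv(cov), diff)
        out[:, i] = np.log(model.priors[i]) - 0.5 * logdet - 0.5 * maha
    return out


def qda_predict(model: QDAModel, X) -> np.ndarray:
    scores = qda_log_discriminants(model, X)
    return np.array([model.classes[i] for i in np.argmax(scores, axis=1)])


@dataclass
class NBModel:
    classes: list[str]
    means: np.ndarray       # (K, d)
    variances: np.ndarray   # (K, d), floored
    priors: np.ndarray


def nb_fit(X, labels, var_floor: float = 1e-9) -> NBModel:
    X, labels, classes = _check_fit_inputs(X, labels)
    means, variances, priors = [], [], []
    for c in classes:
        sub = X[labels == c]
        means.append(sub.mean(axis=0))
        variances.append(np.maximum(sub.var(axis=0, ddof=1), var_floor))
        priors.append(len(sub))
    priors = np.array(priors, dtype=float)
    return NBModel(classes, np.vstack(means), np.vstack(variances), priors / priors.sum())


def nb_log_posterior(model: NBModel, X) -> np.ndarray:
    """Unnormalized log posterior ln p(C_k) + sum_i ln N(x_i; mu_ki, var_ki)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], len(model.classes)))
    for i in range(len(model.classes)):
        var = model.variances[i]
        ll = -0.5 * (np.log(2 * np.pi * var) + (X - model.means[i]) ** 2 / var)
        out[:, i] = np.log(model.priors[i]) + ll.sum(axis=1)
    return out


def nb_predict(model: NBModel, X) -> np.ndarray:
    scores = nb_log_posterior(model, X)
    return np.array([model.classes[i] for i in np.argmax(scores, axis=1)])


# ---------------------------------------------------------------------------
# k-nearest neighbors


@dataclass
class KNNModel:
    classes: list[str]
    train_X: np.ndarray
    train_labels: np.ndarray
    k: int


def knn_fit(X, labels, k: int = 5) -> KNNModel:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if not (1 <= k <= X.shape[0]):
        raise ValueError("k must be in [1, n_train]")
    return KNNModel(_class_order(labels), X.copy(), labels.copy(), k)


def knn_predict(model: KNNModel, X, chunk: int = 2048) -> np.ndarray:
    """Majority vote among the k nearest training points.

    Ties break by smaller mean neighbor distance within the tied classes,
    then by class order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    class_idx = {c: i for i, c in enumerate(model.classes)}
    train_idx = np.array([class_idx[c] for c in model.train_labels])
    out = np.empty(X.shape[0], dtype=object)
    for start in range(0, X.shape[0], chunk):
        block = X[start : start + chunk]
        dist = cdist(block, model.train_X)
        nearest = np.argpartition(dist, model.k - 1, axis=1)[:, : model.k]
        for r in range(block.shape[0]):
            nb = nearest[r]
            votes = np.bincount(train_idx[nb], minlength=len(model.classes))
            top = votes.max()
            tied = np.nonzero(votes == top)[0]
            if tied.size == 1:
                winner = tied[0]
            else:
                dists = dist[r, nb]
                mean_d = [dists[train_idx[nb] == t].mean() for t in tied]
                winner = tied[int(np.argmin(mean_d))]
            out[start + r] = model.classes[winner]
    return out.astype(str)


# ---------------------------------------------------------------------------
# CART


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    counts: np.ndarray | None = None  # leaf class counts

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class CARTModel:
    classes: list[str]
    root: _Node
    max_depth: int
    min_leaf: int
    criterion: str


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return 1.0 - float(p @ p)


def _best_split(X, y_idx, k, min_leaf, criterion):
    """Best (feature, threshold, score); score lower is better."""
    n = X.shape[0]
    best = (None, 0.0, np.inf)
    total = np.bincount(y_idx, minlength=k).astype(float)
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y_idx[order]
        onehot = np.zeros((n, k))
        onehot[np.arange(n), ys] = 1.0
        left_counts = np.cumsum(onehot, axis=0)  # counts with <= position i in left
        # candidate split after position i (left size i+1), only where value changes
        valid = np.nonzero(xs[:-1] < xs[1:])[0]
        valid = valid[(valid + 1 >= min_leaf) & (n - valid - 1 >= min_leaf)]
        if valid.size == 0:
            continue
        lc = left_counts[valid]
        rc = total[None, :] - lc
        ln = lc.sum(axis=1)
        rn = rc.sum(axis=1)
        if criterion == "gini":
            gl = 1.0 - (lc**2).sum(axis=1) / ln**2
            gr = 1.0 - (rc**2).sum(axis=1) / rn**2
            score = (ln * gl + rn * gr) / n
        else:  # chi2: maximize the chi-square statistic of the 2xK table
            expected_l = ln[:, None] * total[None, :] / n
            expected_r = rn[:, None] * total[None, :] / n
            with np.errstate(divide="ignore", invalid="ignore"):
                chi = np.where(expected_l > 0, (lc - expected_l) ** 2 / expected_l, 0.0).sum(axis=1)
                chi += np.where(expected_r > 0, (rc - expected_r) ** 2 / expected_r, 0.0).sum(axis=1)
            score = -chi
        j = int(np.argmin(score))
        if score[j] < best[2]:
            pos = valid[j]
            thr = 0.5 * (xs[pos] + xs[pos + 1])
            best = (f, float(thr), float(score[j]))
    return best


def _grow(X, y_idx, k, depth, max_depth, min_leaf, criterion) -> _Node:
    counts = np.bincount(y_idx, minlength=k).astype(float)
    node = _Node(counts=counts)
    if depth >= max_depth or counts.max() == counts.sum() or len(y_idx) < 2 * min_leaf:
        return node
    f, thr, score = _best_split(X, y_idx, k, min_leaf, criterion)
    if f is None or (criterion == "gini" and score >= _gini(counts) - 1e-12):
        return node
    mask = X[:, f] <= thr
    node.feature, node.threshold = f, thr
    node.left = _grow(X[mask], y_idx[mask], k, depth + 1, max_depth, min_leaf, criterion)
    node.right = _grow(X[~mask], y_idx[~mask], k, depth + 1, max_depth, min_leaf, criterion)
    return node


def cart_fit(
    X,
    labels,
    max_depth: int = 20,
    min_leaf: int = 5,
    criterion: str = "gini",
) -> CARTModel:
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    if criterion not in ("gini", "chi2"):
        raise ValueError("criterion must be 'gini' or 'chi2'")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = _class_order(labels)
    class_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_idx[c] for c in labels])
    root = _grow(X, y_idx, len(classes), 0, max_depth, min_leaf, criterion)
    return CARTModel(classes, root, max_depth, min_leaf, criterion)


def cart_predict(model: CARTModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(X.shape[0], dtype=object)
    for i, row in enumerate(X):
        node = model.root
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        out[i] = model.classes[int(np.argmax(node.counts))]
    return out.astype(str)


# ---------------------------------------------------------------------------
# classifier registry


@dataclass
class Classifier:
    """A (fit, predict) pair with fixed hyperparameters."""

    name: str
    params: dict = field(default_factory=dict)
    model: object = None

    def fit(self, X, labels) -> "Classifier":
        fitters = {
            "lda": lda_fit,
            "qda": qda_fit,
            "nb": nb_fit,
            "knn": knn_fit,
            "cart": cart_fit,
        }
        if self.name not in fitters:
            raise ValueError(f"unknown classifier {self.name!r}")
        self.model = fitters[self.name](X, labels, **self.params)
        return self

    def predict(self, X) -> np.ndarray:
        predictors = {
            "lda": lda_predict,
            "qda": qda_predict,
            "nb": nb_predict,
            "knn": knn_predict,
            "cart": cart_predict,
        }
        if self.model is None:
            raise RuntimeError("classifier not fitted")
        return predictors[self.name](self.model, X)


def make_classifier(name: str, params: dict | None = None) -> Classifier:
    return Classifier(name, dict(params or {}))


# ---------------------------------------------------------------------------
# split protocol


@dataclass
class SplitPlan:
    train_indices: np.ndarray
    test_indices: np.ndarray
    train_fraction: float
    unit: str
    seed: int


def make_split(
    labels,
    meta: pd.DataFrame | None = None,
    train_fraction: float = 0.2,
    unit: str = "spectrum",
    seed: int = 0,
) -> SplitPlan:
    """Stratified random train/test split.

    ``unit='spectrum'`` stratifies by class over individual spectra (the
    per-class training share is within one spectrum of
    ``train_fraction x class size``).  ``unit='sample'`` keeps whole
    physical samples together, so no sample contributes to both sides
    (requires ``meta`` with a ``sample_id`` column).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if unit not in ("spectrum", "sample"):
        raise ValueError("unit must be 'spectrum' or 'sample'")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = _class_order(labels)
    train_idx: list[np.ndarray] = []

    if unit == "spectrum":
        for c in classes:
            idx = np.nonzero(labels == c)[0]
            n_train = int(round(train_fraction * idx.size))
            n_train = min(max(n_train, 1), idx.size - 1)
            train_idx.append(rng.permutation(idx)[:n_train])
    else:
        if meta is None or "sample_id" not in meta.columns:
            raise ValueError("unit='sample' requires meta with a sample_id column")
        sample_ids = meta["sample_id"].to_numpy()
        for c in classes:
            cls_samples = pd.unique(sample_ids[labels == c])
            n_train = int(round(train_fraction * cls_samples.size))
            n_train = min(max(n_train, 1), cls_samples.size - 1) if cls_samples.size > 1 else 1
            chosen = set(rng.permutation(cls_samples)[:n_train].tolist())
            train_idx.append(
                np.nonzero((labels == c) & np.isin(sample_ids, list(chosen)))[0]
            )

    train = np.sort(np.concatenate(train_idx))
    mask = np.zeros(labels.size, dtype=bool)
    mask[train] = True
    test = np.nonzero(~mask)[0]
    for c in classes:
        if not np.any(labels[train] == c):
            raise ValueError(f"class {c!r} absent from the training split")
        if not np.any(labels[test] == c):
            raise ValueError(f"class {c!r} absent from the test split")
    return SplitPlan(train, test, train_fraction, unit, seed)


def repeated_evaluation(
    X,
    labels,
    classifier: Classifier | str,
    n_repeats: int = 20,
    train_fraction: float = 0.2,
    unit: str = "spectrum",
    meta: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict:
    """Mean accuracy +/- sample SD over R independent stratified splits."""
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats for a sample SD")
    if isinstance(classifier, str):
        classifier = make_classifier(classifier)
    X = _feature_values(X)
    labels = np.asarray(labels)
    seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    accuracies = np.empty(n_repeats)
    for r in range(n_repeats):
        plan = make_split(labels, meta, train_fraction, unit, int(seeds[r]))
        clf = make_classifier(classifier.name, classifier.params)
        clf.fit(X[plan.train_indices], labels[plan.train_indices])
        pred = clf.predict(X[plan.test_indices])
        accuracies[r] = float(np.mean(pred == labels[plan.test_indices]))
    return {
        "classifier": classifier.name,
        "mean_accuracy": float(accuracies.mean()),
        "sd_accuracy": float(accuracies.std(ddof=1)),
        "accuracies": accuracies,
    }


def _feature_values(X) -> np.ndarray:
    from .features import FeatureMatrix

    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)
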