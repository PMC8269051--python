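"""Latent codes as radiomics-style features.

Flattened digital signatures feed two downstream analyses: a 2-D PCA
embedding for visual structure (mean centering only — the latent space is
already pulled toward N(0, 1) during training, so no per-feature scaling
is applied) and cross-validated lesion-vs-normal classification with four
out-of-the-box classifiers (linear SVM, random forest with 1000 trees of
max depth 10, MLP, Gaussian naive Bayes). Metrics are accuracy,
sensitivity, specificity and ROC AUC, reported per classifier with a
dispersion of two standard deviations across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import sklearn.base
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .model import NetworkBundle, encode

__all__ = [
    "CLASSIFIERS", "ClassifierReport", "flatten_latent", "unflatten_latent",
    "latent_features", "pca_embed", "compute_metrics", "crossval_classify",
]

CLASSIFIERS = ("svm", "rf", "mlp", "nb")


def flatten_latent(latent: np.ndarray) -> np.ndarray:
    """Flatten an ``(S, S, C)`` latent row-major (cells, then channels).

    The ordering is C-contiguous, so entry ``(i, j, k)`` lands at position
    ``(i * S_w + j) * C + k``; :func:`unflatten_latent` inverts it exactly.
    """
    latent = np.asarray(latent)
    if latent.ndim == 3:
        return latent.reshape(-1).copy()
    if latent.ndim == 4:  # batch
        return latent.reshape(latent.shape[0], -1).copy()
    raise ValueError(f"expected (S, S, C) or (n, S, S, C), got {latent.shape}")


def unflatten_latent(vec: np.ndarray,
                     latent_shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`flatten_latent`."""
    return np.asarray(vec).reshape(latent_shape).copy()


def latent_features(patches: np.ndarray, bundle: NetworkBundle,
                    batch_size: int = 64) -> np.ndarray:
    """Encode a patch stack and flatten: ``(n, S*S*C)`` feature matrix."""
    feats = []
    for start in range(0, len(patches), batch_size):
        z = encode(patches[start:start + batch_size], bundle)
        feats.append(flatten_latent(z))
    return np.concatenate(feats)


def pca_embed(features: np.ndarray, k: int = 2
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA with mean centering only (no per-feature scaling).

    Returns ``(scores, components, explained_variance_ratio)`` with
    ``scores`` of shape ``(n, k)`` (zero column means), orthonormal
    ``components`` of shape ``(k, d)`` and non-increasing variance
    fractions.
    """
    features = np.asarray(features, dtype=float)
    n, d = features.shape
    if k > min(n - 1, d):
        raise ValueError(
            f"k = {k} exceeds min(n_samples - 1, n_features) = "
            f"{min(n - 1, d)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(features)
    return scores, pca.components_, pca.explained_variance_ratio_


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    y_score: np.ndarray
                    ) -> tuple[float, float, float, float]:
    """Accuracy, sensitivity, specificity, ROC AUC for binary labels.

    SE = TP/(TP+FN) over the lesion class, SP = TN/(TN+FP) over normals;
    AUC is the probability that a random positive outscores a random
    negative with ties counted 1/2. With a single-class ``y_true`` the
    undefined entries are returned as NaN with a warning.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    n = len(y_true)
    acc = (tp + tn) / n
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("single-class y_true: sensitivity/specificity/AUC "
                      "undefined, returning NaN", stacklevel=2)
        se = tp / (tp + fn) if tp + fn else float("nan")
        sp = tn / (tn + fp) if tn + fp else float("nan")
        return acc, se, sp, float("nan")
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    auc = float(roc_auc_score(y_true, y_score))
    return acc, se, sp, auc


@dataclass(frozen=True)
class ClassifierReport:
    """Cross-validated metrics for one classifier.

    Each metric is the mean across folds; ``dispersion`` holds two
    standard deviations across folds per metric.
    """

    classifier: str
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    dispersion: dict[str, float] = field(default_factory=dict)
    k_folds: int = 10
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "dispersion": dict(self.dispersion),
            "k_folds": self.k_folds,
            "seed": self.seed,
        }


def _build_classifier(name: str, seed: int):
    if name == "svm":
        return LinearSVC(random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=1000, max_depth=10,
                                      random_state=seed)
    if name == "mlp":
        return MLPClassifier(random_state=seed)
    if name == "nb":
        return GaussianNB()
    raise ValueError(
        f"unknown classifier {name!r}; supported: {', '.join(CLASSIFIERS)}")


def _scores(clf, x: np.ndarray) -> np.ndarray:
    # margin for SVM-like models, positive-class posterior otherwise
    if hasattr(clf, "decision_function"):
        return clf.decision_function(x)
    return clf.predict_proba(x)[:, 1]


def crossval_classify(features: np.ndarray, labels: np.ndarray,
                      classifier: str = "svm", k_folds: int = 10,
                      seed: int = 0) -> ClassifierReport:
    """Stratified k-fold cross-validation of one classifier.

    Folds are deterministic under ``seed``. Each class must have at least
    ``k_folds`` members. Per-fold ACC/SE/SP/AUC are aggregated as mean
    with a 2-sd dispersion.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(features) != len(labels):
        raise ValueError("feature rows and labels differ in length")
    for cls in (0, 1):
        if np.sum(labels == cls) < k_folds:
            raise ValueError(
                f"class {cls} has fewer members than k_folds = {k_folds}")
    clf_proto = _build_classifier(classifier, seed)

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        for train_idx, test_idx in skf.split(features, labels):
            clf = sklearn.base.clone(clf_proto)
            clf.fit(features[train_idx], labels[train_idx])
            y_pred = clf.predict(features[test_idx])
            y_score = _scores(clf, features[test_idx])
            rows.append(compute_metrics(labels[test_idx], y_pred, y_score))
    arr = np.array(rows)  # (k, 4)
    means = arr.mean(axis=0)
    disp = 2.0 * arr.std(axis=0)
    names = ("accuracy", "sensitivity", "specificity", "auc")
    return ClassifierReport(
        classifier=classifier,
        accuracy=float(means[0]), sensitivity=float(means[1]),
        specificity=float(means[2]), auc=float(means[3]),
        dispersion={k: float(v) for k, v in zip(names, disp)},
        k_folds=k_folds, seed=seed,
    )
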