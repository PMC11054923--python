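"""Classifier training, stratified cross-validation and confusion matrices.

Three standard classifiers are compared on raw (unscaled) feature subsets:
k-nearest neighbours (KNN), linear discriminant analysis (LDA) and a
support-vector machine (SVM).  Hyperparameter defaults: KNN k=5 with
Euclidean distance; SVM with RBF kernel and the scale-adaptive gamma
1/(d * Var(X)) plus a soft margin penalty C=100 — both matter because the
features are deliberately left unscaled, so the kernel must adapt to the
raw µV magnitudes and the margin penalty must stay permissive; LDA via the
singular-value-decomposition solver, which tolerates singular within-class
covariance on small subsets.  Performance is
quantified by stratified, seed-shuffled 5-fold cross-validation
accumulated into a single multiclass confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = [
    "ALGORITHMS",
    "ClassifierSpec",
    "ConfusionMatrix",
    "ActionCounts",
    "make_estimator",
    "train_classifier",
    "crossvalidate",
    "confusion_to_counts",
]

ALGORITHMS: tuple[str, ...] = ("knn", "lda", "svm")

_DEFAULT_HYPERPARAMS = {
    "knn_k": 5,
    "svm_kernel": "rbf",
    "svm_c": 100.0,
    "svm_gamma": "scale",
    "lda_solver": "svd",
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice plus hyperparameters and a shuffling seed."""

    algorithm: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        hp = {**_DEFAULT_HYPERPARAMS, **self.hyperparams}
        if hp["knn_k"] < 1:
            raise ValueError("knn_k must be >= 1")
        if hp["svm_c"] <= 0:
            raise ValueError("svm_c must be > 0")
        object.__setattr__(self, "hyperparams", hp)


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 (or CxC) counts; rows = true action, columns = predicted."""

    counts: np.ndarray
    action_order: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if c.shape[0] != len(self.action_order):
            raise ValueError("matrix size must match action_order")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class ActionCounts:
    """One-vs-rest TP/TN/FP/FN tally for a single action."""

    action: str
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def make_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for ``spec``."""
    hp = spec.hyperparams
    if spec.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=int(hp["knn_k"]))
    if spec.algorithm == "lda":
        return LinearDiscriminantAnalysis(solver=hp["lda_solver"])
    return SVC(kernel=hp["svm_kernel"], C=float(hp["svm_c"]),
               gamma=hp["svm_gamma"], random_state=spec.seed)


class TrainedClassifier:
    """A fitted estimator bound to the feature subset it was trained on."""

    def __init__(self, estimator, feature_subset: tuple[str, ...],
                 action_order: tuple[str, ...]):
        self.estimator = estimator
        self.feature_subset = feature_subset
        self.action_order = action_order

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_subset):
            raise ValueError(
                f"expected {len(self.feature_subset)} features, got {X.shape[1]}")
        return self.estimator.predict(X)


def _check_training_inputs(table: FeatureTable,
                           feature_subset: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    if not feature_subset:
        raise ValueError("feature subset must be non-empty")
    X = table.matrix(feature_subset)  # raises KeyError on unknown names
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    return X, y


def train_classifier(table: FeatureTable, spec: ClassifierSpec,
                     feature_subset: Sequence[str]) -> TrainedClassifier:
    """Fit one classifier on the full table restricted to ``feature_subset``."""
    X, y = _check_training_inputs(table, feature_subset)
    est = make_estimator(spec)
    est.fit(X, y)
    order = tuple(dict.fromkeys(table.labels))
    return TrainedClassifier(est, tuple(feature_subset), order)


def crossvalidate(table: FeatureTable, spec: ClassifierSpec,
                  feature_subset: Sequence[str], n_folds: int = 5,
                  group_by_session: bool = False) -> ConfusionMatrix:
    """Stratified k-fold cross-validation accumulated into one matrix.

    Folds are stratified by action and shuffled under ``spec.seed``; each
    sample is predicted exactly once while held out, so the matrix total
    equals the number of rows.  ``group_by_session`` switches to
    session-grouped folds to guard against within-session leakage.
    """
    X, y = _check_training_inputs(table, feature_subset)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"every class needs >= {n_folds} members for {n_folds}-fold CV "
            f"(smallest has {counts.min()})")
    order = tuple(dict.fromkeys(table.labels))

    if group_by_session:
        splitter = GroupKFold(n_splits=n_folds)
        splits = splitter.split(X, y, groups=table.frame["session"])
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=spec.seed)
        splits = splitter.split(X, y)

    cm = np.zeros((len(order), len(order)), dtype=int)
    for train_idx, test_idx in splits:
        est = make_estimator(spec)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        cm += skmetrics.confusion_matrix(y[test_idx], pred, labels=list(order))
    return ConfusionMatrix(counts=cm, action_order=order)


def confusion_to_counts(cm: ConfusionMatrix, action: str) -> ActionCounts:
    """Collapse a multiclass matrix to one action's TP/TN/FP/FN."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if action not in cm.action_order:
        raise ValueError(f"unknown action {action!r}")
    i = cm.action_order.index(action)
    c = cm.counts
    tp = int(c[i, i])
    fn = int(c[i, :].sum()) - tp
    fp = int(c[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return ActionCounts(action=action, TP=tp, TN=tn, FP=fp, FN=fn)
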