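"""Stratified cross-validated classification and evaluation metrics.

Evaluation follows the benchmark protocol: stratified 4-fold cross-validation
(three folds train, one tests; every fold tests once), six classifiers from
the comparison study, macro-averaged one-vs-rest accuracy / precision /
recall / specificity / F1 per fold, and the chance accuracy of a
proportion-matched random guesser, 100 * sum_i p_i^2.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_NAMES",
    "EvaluationReport",
    "make_classifier",
    "stratified_folds",
    "train_and_eval",
    "chance_accuracy",
    "compute_metrics",
]

CLASSIFIER_NAMES = (
    "fine_knn",
    "subspace_knn",
    "ld",
    "subspace_discriminant",
    "lsvm",
    "qsvm",
)

#: mapping of the comparison study's learner names onto scikit-learn estimators;
#: subspace ensembles use 30 learners on random feature subsets of half size.
SUBSPACE_LEARNERS = 30
SUBSPACE_FRACTION = 0.5


class _RandomSubspace(BaggingClassifier):
    """Random-subspace ensemble: each learner sees half the features.

    The subspace size is resolved at fit time so that datasets with very few
    features still train (at least one feature per learner).
    """

    def fit(self, X, y, **kwargs):
        n_features = np.asarray(X).shape[1]
        self.max_features = max(1, int(round(SUBSPACE_FRACTION * n_features)))
        return super().fit(X, y, **kwargs)


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the six benchmark classifiers by name."""
    if name == "fine_knn":
        return KNeighborsClassifier(n_neighbors=1)
    if name == "subspace_knn":
        return _RandomSubspace(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=SUBSPACE_LEARNERS,
            bootstrap=False,
            random_state=seed,
        )
    if name == "ld":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if name == "subspace_discriminant":
        return _RandomSubspace(
            estimator=LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
            n_estimators=SUBSPACE_LEARNERS,
            bootstrap=False,
            random_state=seed,
        )
    if name == "lsvm":
        return SVC(kernel="linear", C=1.0)
    if name == "qsvm":
        return SVC(kernel="poly", degree=2, coef0=1.0, C=1.0)
    raise ValueError(f"unknown classifier {name!r}; valid: {list(CLASSIFIER_NAMES)}")


# ---------------------------------------------------------------------------
# Folds and metrics


def stratified_folds(labels: Sequence[str], k: int = 4, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``k`` stratified folds.

    Per-class counts across folds differ by at most one.  Every class must
    have at least ``k`` members.  Returns an int array of fold indices.
    """
    labels = np.asarray(labels)
    counts = Counter(labels.tolist())
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise ValueError(
            f"class(es) {sorted(small)} have fewer than {k} members; "
            f"cannot build {k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def chance_accuracy(class_counts: Sequence[int]) -> float:
    """Expected accuracy (%) of a guesser matching the class proportions.

    100 * sum_i p_i^2 for class proportions p_i; 100 for a single class and
    100 / C for C balanced classes.
    """
    counts = np.asarray(list(class_counts), dtype=np.float64)
    if counts.size == 0:
        raise ValueError("class_counts is empty")
    if np.any(counts <= 0):
        raise ValueError("class counts must be positive")
    p = counts / counts.sum()
    return float(100.0 * np.sum(p**2))


def compute_metrics(cm: np.ndarray) -> dict:
    """Macro-averaged one-vs-rest rates (%) from a square confusion matrix.

    Rows are true classes, columns predictions.  Precision of a class that is
    never predicted is defined as 0 and flagged in ``undefined_precision``.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")

    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    pred_counts = tp + fp
    undefined = pred_counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(undefined, 0.0, tp / np.where(undefined, 1.0, pred_counts))
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1.0), 0.0)
        specificity = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1.0), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr == 0, 1.0, pr), 0.0)

    if np.any(undefined):
        logger.warning(
            "class(es) %s never predicted; precision set to 0",
            np.flatnonzero(undefined).tolist(),
        )
    return {
        "accuracy": float(100.0 * tp.sum() / total),
        "precision": float(100.0 * precision.mean()),
        "recall": float(100.0 * recall.mean()),
        "specificity": float(100.0 * specificity.mean()),
        "f1": float(100.0 * f1.mean()),
        "undefined_precision": np.flatnonzero(undefined).tolist(),
    }


# ---------------------------------------------------------------------------
# Cross-validated evaluation


@dataclass
class EvaluationReport:
    """Per-fold and mean metrics for one classifier / feature combination."""

    classifier_name: str
    feature_kind: str
    classes: list[str]
    fold_metrics: list[dict]
    mean_metrics: dict
    confusion_matrix: list[list[int]]  # summed over folds
    chance_accuracy: float
    fold_predictions: list[dict] = field(default_factory=list, repr=False)

    @property
    def mean_accuracy(self) -> float:
        return self.mean_metrics["accuracy"]

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


FeatureBuilder = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


def train_and_eval(
    classifier_name: str,
    features,
    labels: Sequence[str],
    folds: np.ndarray,
    feature_kind: str = "specgmm",
    standardize: bool = True,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """Fit and evaluate one classifier across the given fold assignment.

    ``features`` is either a fixed (n_samples, d) matrix, or a callable
    ``(train_idx, test_idx) -> (X_train, X_test)`` for feature spaces that
    must be rebuilt per fold from training data only (distance-matrix
    features, or supervectors under a training-fold UBM).  Feature
    standardization, when enabled, is fitted on the training fold only.
    """
    labels = np.asarray(labels)
    folds = np.asarray(folds)
    classes = sorted(set(labels.tolist()))
    n_folds = int(folds.max()) + 1
    cm_total = np.zeros((len(classes), len(classes)), dtype=np.int64)
    fold_metrics = []
    fold_predictions = []

    for fold in range(n_folds):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        if callable(features):
            X_train, X_test = features(train_idx, test_idx)
        else:
            X = np.asarray(features, dtype=np.float64)
            X_train, X_test = X[train_idx], X[test_idx]
        y_train, y_test = labels[train_idx], labels[test_idx]

        if standardize:
            scaler = StandardScaler()
            X_train = scaler.fit_transform(X_train)
            X_test = scaler.transform(X_test)

        clf = make_classifier(classifier_name, seed=seed + fold)
        clf.fit(X_train, y_train)
        y_pred = clf.predict(X_test)

        cm = _sk_confusion(y_test, y_pred, labels=classes)
        cm_total += cm
        fold_metrics.append(compute_metrics(cm))
        if sample_ids is not None:
            ids = np.asarray(sample_ids)[test_idx]
            fold_predictions.extend(
                {"id": str(i), "fold": fold, "true": str(t), "predicted": str(p)}
                for i, t, p in zip(ids, y_test, y_pred)
            )

    mean_metrics = {
        key: float(np.mean([m[key] for m in fold_metrics]))
        for key in ("accuracy", "precision", "recall", "specificity", "f1")
    }
    counts = [int((labels == c).sum()) for c in classes]
    return EvaluationReport(
        classifier_name=classifier_name,
        feature_kind=feature_kind,
        classes=classes,
        fold_metrics=fold_metrics,
        mean_metrics=mean_metrics,
        confusion_matrix=cm_total.tolist(),
        chance_accuracy=chance_accuracy(counts),
        fold_predictions=fold_predictions,
    )
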