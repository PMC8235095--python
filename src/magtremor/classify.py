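"""k-NN classification of tapping takes.

The protocol mirrors a standard clinical-screening evaluation: a k-nearest
neighbor classifier (k = 10, Euclidean distance on z-score standardized
features) assessed by stratified 5-fold cross-validation, reporting the mean
held-out accuracy in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = ["FeatureDataset", "knn_cv", "knn_cv_report"]

DEFAULT_SUBSET = ("int1_4", "int4_12")


@dataclass(frozen=True)
class FeatureDataset:
    """Feature matrix + labels for a chosen feature subset."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain missing/non-finite values")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2 or np.min(counts) < 2:
            raise ValueError("need at least 2 rows per class")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @classmethod
    def from_features(cls, features, subset=DEFAULT_SUBSET) -> "FeatureDataset":
        """Build from a list of TapFeatures-like records with a label field."""
        X = np.array([f.subset(subset) for f in features])
        y = np.array([f.label for f in features])
        return cls(X=X, y=y, feature_names=tuple(subset))


def _pipeline(k: int):
    return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=k))


def _cv(folds: int, seed: int) -> StratifiedKFold:
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


def knn_cv(dataset: FeatureDataset, k: int = 10, folds: int = 5,
           seed: int = 0) -> float:
    """Mean cross-validated accuracy, percent.

    Folds are stratified and seeded; k neighbors must fit inside every
    training split.
    """
    n = len(dataset.y)
    if n < folds:
        raise ValueError("fewer rows than folds")
    if k > n - int(np.ceil(n / folds)):
        raise ValueError("k exceeds the smallest training-fold size")
    scores = cross_val_score(
        _pipeline(k), dataset.X, dataset.y, cv=_cv(folds, seed), scoring="accuracy"
    )
    return float(np.mean(scores) * 100.0)


def knn_cv_report(dataset: FeatureDataset, k: int = 10, folds: int = 5,
                  seed: int = 0) -> dict:
    """Per-fold accuracies, mean accuracy and pooled confusion matrix."""
    scores = cross_val_score(
        _pipeline(k), dataset.X, dataset.y, cv=_cv(folds, seed), scoring="accuracy"
    )
    pred = cross_val_predict(_pipeline(k), dataset.X, dataset.y,
                             cv=_cv(folds, seed))
    classes = sorted(np.unique(dataset.y).tolist())
    cm = confusion_matrix(dataset.y, pred, labels=classes)
    return {
        "features": list(dataset.feature_names),
        "k": k,
        "folds": folds,
        "seed": seed,
        "fold_accuracy_percent": [float(s * 100.0) for s in scores],
        "mean_accuracy_percent": float(np.mean(scores) * 100.0),
        "classes": classes,
        "confusion_matrix": cm.tolist(),
    }
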