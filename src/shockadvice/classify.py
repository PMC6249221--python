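"""Secondary learning: the six conventional classifiers on deep features.

The deep feature vector (first-FC activations of a trained CNNE) is fed to a
conventional learner; the shock-advice default is Boosting (BS), realized as
AdaBoost over depth-1 decision trees.  The secondary learner re-learns the
class structure from the feature geometry instead of trusting the CNN's own
softmax, which is what lifts sensitivity on the shockable class.

All six families are scikit-learn estimators behind a uniform spec; the
pipeline's contribution is upstream (channel construction and feature
learning), not these learners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ClassifierSpec", "make_classifier", "train_classifier", "predict",
           "CLASSIFIER_NAMES"]

CLASSIFIER_NAMES = ("SVM", "KNN", "RF", "BG", "BS", "LR")


@dataclass
class ClassifierSpec:
    """One of the six conventional families with its hyperparameters.

    ``name`` is one of SVM, KNN, RF, BG (bagging), BS (boosting — the SAA
    default), LR.  ``standardize`` optionally z-scores features first (off by
    default).  ``params`` overrides the conventional defaults below.
    """

    name: str = "BS"
    params: dict = field(default_factory=dict)
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"classifier must be one of {CLASSIFIER_NAMES}, got {self.name!r}"
            )


def make_classifier(spec: ClassifierSpec):
    """Instantiate the (unfitted) scikit-learn estimator for a spec."""
    name, p, seed = spec.name, spec.params, spec.seed
    if name == "SVM":
        est = SVC(C=p.get("C", 1.0), kernel=p.get("kernel", "rbf"),
                  gamma=p.get("gamma", "scale"), random_state=seed)
    elif name == "KNN":
        est = KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 5))
    elif name == "RF":
        est = RandomForestClassifier(n_estimators=p.get("n_estimators", 100),
                                     random_state=seed)
    elif name == "BG":
        est = BaggingClassifier(n_estimators=p.get("n_estimators", 100),
                                random_state=seed)
    elif name == "BS":
        est = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=p.get("max_depth", 1)),
            n_estimators=p.get("n_estimators", 100),
            random_state=seed,
        )
    else:  # LR
        est = LogisticRegression(C=p.get("C", 1.0), max_iter=p.get("max_iter", 1000))
    if spec.standardize:
        return make_pipeline(StandardScaler(), est)
    return est


def train_classifier(spec: ClassifierSpec, features: np.ndarray, labels: np.ndarray):
    """Fit the spec's estimator on a feature matrix; deterministic given seed."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D (n_segments, n_features) matrix")
    if len(x) != len(y):
        raise ValueError("feature/label length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = make_classifier(spec)
    clf.fit(x, y)
    return clf


def predict(classifier, features: np.ndarray) -> np.ndarray:
    """SH/NSH labels (1/0), one per feature vector."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[None]
    return classifier.predict(x).astype(int)


def clone_classifier(classifier):
    """Unfitted copy with identical hyperparameters (per-fold retraining)."""
    return clone(classifier)
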