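"""Binary classification with stratified three-fold cross-validation.

Five classifier families are supported — regularized multinomial logistic
regression (the SoftMax head), decision tree, random forest, k-nearest
neighbors and an RBF support-vector machine.  Standardization is fitted
inside each training fold, class 2 (the high-grade lesion) is the positive
class, and per-fold confusion counts are reported together with pooled
counts and the best fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import ConfusionCounts, MetricSet, compute_metrics

__all__ = ["CLASSIFIERS", "CVResult", "make_classifier", "fit_classifier",
           "train_eval_cv", "score_slices"]

CLASSIFIERS = ("softmax", "dt", "rf", "knn", "svm")
POSITIVE_CLASS = 2


def make_classifier(name: str, seed: int = 0) -> Pipeline:
    """A seeded scaler+estimator pipeline for one of the five families."""
    if name == "softmax":
        est = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    elif name == "dt":
        est = DecisionTreeClassifier(criterion="gini", random_state=seed)
    elif name == "rf":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif name == "knn":
        est = KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    elif name == "svm":
        # gamma="auto" is 1/n_features on standardized inputs
        est = SVC(kernel="rbf", C=1.0, gamma="auto", random_state=seed)
    else:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


@dataclass
class CVResult:
    classifier: str
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[MetricSet]
    best_fold: int
    pooled: ConfusionCounts
    pooled_metrics: MetricSet
    seed: int

    @property
    def pooled_accuracy(self) -> float:
        return self.pooled_metrics.ac

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "seed": self.seed,
            "best_fold": self.best_fold,
            "folds": [
                {"TP": c.tp, "FN": c.fn, "TN": c.tn, "FP": c.fp,
                 **{k: v for k, v in m.rounded().items()}}
                for c, m in zip(self.fold_counts, self.fold_metrics)
            ],
            "pooled": {"TP": self.pooled.tp, "FN": self.pooled.fn,
                       "TN": self.pooled.tn, "FP": self.pooled.fp,
                       **self.pooled_metrics.rounded()},
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos = y_true == POSITIVE_CLASS
    pred_pos = y_pred == POSITIVE_CLASS
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)), fn=int(np.sum(pos & ~pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)), fp=int(np.sum(~pos & pred_pos)),
    )


def train_eval_cv(features: np.ndarray, labels: np.ndarray, classifier: str,
                  seed: int = 0, folds: int = 3) -> CVResult:
    """Stratified k-fold (default 3) fit/evaluate cycle with per-fold counts."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] < 4 * folds:
        raise ValueError(f"need at least {4 * folds} samples for {folds}-fold CV")
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[MetricSet] = []
    for train_idx, test_idx in skf.split(X, y):
        model = make_classifier(classifier, seed=seed)
        model.fit(X[train_idx], y[train_idx])
        counts = _confusion(y[test_idx], model.predict(X[test_idx]))
        fold_counts.append(counts)
        fold_metrics.append(compute_metrics(counts))

    accs = [m.ac for m in fold_metrics]
    best_fold = int(np.argmax(accs))  # argmax takes the lowest index on ties
    pooled = fold_counts[0]
    for c in fold_counts[1:]:
        pooled = pooled + c
    return CVResult(classifier, fold_counts, fold_metrics, best_fold,
                    pooled, compute_metrics(pooled), seed)


def fit_classifier(features: np.ndarray, labels: np.ndarray, classifier: str,
                   seed: int = 0) -> Pipeline:
    """Fit one seeded classifier pipeline on the full table."""
    model = make_classifier(classifier, seed=seed)
    model.fit(np.asarray(features, dtype=float), np.asarray(labels))
    return model


def score_slices(model: Pipeline, features: np.ndarray) -> np.ndarray:
    """Per-sample positive-class (class 2) score in [0, 1].

    Probabilistic models report the class-2 probability, so thresholding at
    0.5 reproduces their predicted labels; margin models (SVM) report a
    logistic squash of the signed decision value, which preserves ranking
    and keeps the 0.5 threshold at the decision boundary.
    """
    X = np.asarray(features, dtype=float)
    clf = model.named_steps["clf"]
    if model.classes_.size == 1:  # degenerate single-class fit
        const = 1.0 if model.classes_[0] == POSITIVE_CLASS else 0.0
        return np.full(X.shape[0], const)
    if hasattr(clf, "predict_proba"):
        proba = model.predict_proba(X)
        pos_col = int(np.argmax(model.classes_ == POSITIVE_CLASS))
        return proba[:, pos_col]
    margin = model.decision_function(X)
    if model.classes_[1] != POSITIVE_CLASS:  # flip so class 2 scores high
        margin = -margin
    return expit(margin)
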