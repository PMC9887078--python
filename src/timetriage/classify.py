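"""Classifier families and F1-optimizing hyperparameter selection.

Nine classifier families are supported — L1 logistic regression, decision
tree, random forest, k-nearest neighbors, SVM, AdaBoost, gradient boosting,
bagging, and a logistic head over embedding-provider features (the slot that
contextual-embedding classification layers plug into).  For each family a
hyperparameter grid is searched by stratified k-fold cross-validation with
mean F1 on the positive class as the selection score; the winner (ties break
to the first grid candidate in deterministic order) is refit on all rows.

Prediction emits a probability-like score per document; the positive label is
assigned when the score reaches the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import make_scorer, f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .representation import DocMatrix

__all__ = [
    "FAMILIES",
    "DEFAULT_GRIDS",
    "ClassifierSpec",
    "TrainedModel",
    "F1GridSearchClassifier",
    "grid_search_cv",
    "predict_articles",
    "article_level_aggregate",
]

FAMILIES = (
    "l1_logreg",
    "decision_tree",
    "random_forest",
    "knn",
    "svm",
    "adaboost",
    "gradient_boosting",
    "bagging",
    "provider_head",
)

#: Default hyperparameter grids; configuration, not constants.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "l1_logreg": {"C": [0.1, 1.0, 10.0]},
    "decision_tree": {"max_depth": [3, 5, 10, None]},
    "random_forest": {"n_estimators": [100, 300]},
    "knn": {"n_neighbors": [3, 5, 11]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "adaboost": {"n_estimators": [50, 100]},
    "gradient_boosting": {"n_estimators": [100, 200]},
    "bagging": {"n_estimators": [10, 50]},
    "provider_head": {"C": [0.1, 1.0, 10.0]},
}

_NEEDS_DENSE = {"gradient_boosting"}


def _base_estimator(family: str, seed: int):
    if family == "l1_logreg":
        return LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                  random_state=seed, max_iter=5000)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "knn":
        return KNeighborsClassifier()
    if family == "svm":
        return SVC(probability=True, random_state=seed)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if family == "bagging":
        return BaggingClassifier(random_state=seed, n_jobs=1)
    if family == "provider_head":
        # logistic classification head over provider embeddings
        return LogisticRegression(l1_ratio=0.0, solver="lbfgs",
                                  random_state=seed, max_iter=5000)
    raise ValueError(f"unknown classifier family {family!r}; expected one of {FAMILIES}")


@dataclass
class ClassifierSpec:
    """One classifier family plus its search grid and CV settings."""

    family: str
    grid: dict[str, list] | None = None
    cv_folds: int = 5
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


@dataclass
class TrainedModel:
    """A refit best-candidate model with its CV statistics."""

    spec: ClassifierSpec
    chosen_params: dict
    cv_f1_mean: float
    cv_f1_sd: float
    estimator: object
    columns: list[str] | None = None
    classes: tuple = ("negative", "positive")


class F1GridSearchClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style estimator wrapping the F1-optimized grid search.

    Parameters mirror :class:`ClassifierSpec`.  After ``fit``:
    ``best_params_``, ``cv_f1_mean_``, ``cv_f1_sd_``, ``estimator_``.
    ``predict_proba`` returns class probabilities; ``predict`` applies the
    decision threshold to the positive-class score.
    """

    def __init__(self, family: str = "l1_logreg", grid: dict | None = None,
                 cv_folds: int = 5, seed: int = 0, threshold: float = 0.5):
        self.family = family
        self.grid = grid
        self.cv_folds = cv_folds
        self.seed = seed
        self.threshold = threshold

    def _spec(self) -> ClassifierSpec:
        return ClassifierSpec(self.family, None if self.grid is None else dict(self.grid),
                              self.cv_folds, self.seed, self.threshold)

    def fit(self, X, y) -> "F1GridSearchClassifier":
        spec = self._spec()
        y = np.asarray(y, dtype=object)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("labels must contain both classes")
        if counts.min() < spec.cv_folds:
            raise ValueError(
                f"minority class has {counts.min()} rows; need >= cv_folds={spec.cv_folds} "
                "for stratified folds to contain both classes"
            )
        if spec.family in _NEEDS_DENSE and sp.issparse(X):
            X = X.toarray()
        pos_label = "positive" if "positive" in classes else classes[-1]
        scorer = make_scorer(f1_score, pos_label=pos_label, zero_division=0)
        cv = StratifiedKFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
        gs = GridSearchCV(
            _base_estimator(spec.family, spec.seed),
            spec.grid, scoring=scorer, cv=cv, refit=True, n_jobs=1,
        )
        gs.fit(X, y)
        self.best_params_ = dict(gs.best_params_)
        self.cv_f1_mean_ = float(gs.cv_results_["mean_test_score"][gs.best_index_])
        self.cv_f1_sd_ = float(gs.cv_results_["std_test_score"][gs.best_index_])
        self.estimator_ = gs.best_estimator_
        self.classes_ = self.estimator_.classes_
        self.pos_label_ = pos_label
        return self

    def _dense_if_needed(self, X):
        if self.family in _NEEDS_DENSE and sp.issparse(X):
            return X.toarray()
        return X

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class probability (or calibrated score) per row."""
        X = self._dense_if_needed(X)
        proba = self.estimator_.predict_proba(X)
        pos_idx = list(self.estimator_.classes_).index(self.pos_label_)
        return proba[:, pos_idx]

    def predict_proba(self, X) -> np.ndarray:
        X = self._dense_if_needed(X)
        return self.estimator_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        neg = [c for c in self.classes_ if c != self.pos_label_][0]
        return np.where(scores >= self.threshold, self.pos_label_, neg)


def grid_search_cv(X, labels: Sequence[str], spec: ClassifierSpec) -> TrainedModel:
    """Select hyperparameters by stratified CV mean F1 and refit on all rows."""
    columns = None
    if isinstance(X, DocMatrix):
        columns = list(X.columns)
        X = X.values
    clf = F1GridSearchClassifier(spec.family, spec.grid, spec.cv_folds,
                                 spec.seed, spec.threshold)
    clf.fit(X, list(labels))
    return TrainedModel(
        spec=spec,
        chosen_params=clf.best_params_,
        cv_f1_mean=clf.cv_f1_mean_,
        cv_f1_sd=clf.cv_f1_sd_,
        estimator=clf,
        columns=columns,
        classes=tuple(clf.classes_),
    )


def predict_articles(model: TrainedModel, X) -> pd.DataFrame:
    """Score documents; one row (id, score, predicted_label) per input row."""
    ids = None
    if isinstance(X, DocMatrix):
        if model.columns is not None and list(X.columns) != list(model.columns):
            missing = sorted(set(model.columns) - set(X.columns))[:10]
            raise ValueError(
                f"feature columns do not match training space; first missing: {missing}"
            )
        ids = list(X.ids)
        X = X.values
    n = X.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if n == 0:
        return pd.DataFrame(columns=["id", "score", "predicted_label"])
    clf: F1GridSearchClassifier = model.estimator
    scores = clf.decision_scores(X)
    labels = np.where(scores >= model.spec.threshold, "positive", "negative")
    return pd.DataFrame({"id": ids, "score": scores, "predicted_label": labels})


def article_level_aggregate(excerpt_predictions: pd.DataFrame, mode: str = "concat") -> pd.DataFrame:
    """Aggregate per-excerpt predictions to article level.

    ``concat`` is a pass-through (the default pipeline concatenates a
    document's excerpts before featurization, so rows are already per
    article); ``max_score`` keeps the maximum excerpt score per article id.
    """
    if mode == "concat":
        return excerpt_predictions.copy()
    if mode == "max_score":
        idx = excerpt_predictions.groupby("id")["score"].idxmax()
        out = excerpt_predictions.loc[idx].sort_index().reset_index(drop=True)
        return out
    raise ValueError(f"unknown aggregation mode {mode!r}")
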