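"""Binary lesion classification under leave-one-out cross-validation.

Three model families: elastic-net LDA (realized as penalized optimal scoring
of a two-class indicator), elastic-net logistic regression, and gradient-
boosted trees. Hyperparameters are chosen per training fold by an inner
five-fold cross-validated grid search; features are standardized with
training-fold statistics only; out-of-fold scores are pooled, thresholded at
0.5, and summarized as accuracy / sensitivity / specificity / AUC.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_X_y

__all__ = [
    "MODEL_FAMILIES",
    "ElasticNetLDA",
    "ModelSpec",
    "make_model",
    "fit_predict",
    "loocv",
    "metrics",
    "auc",
    "EvaluationResult",
]

MODEL_FAMILIES = ("lda-enet", "logistic-enet", "xgboost")

_LAMBDAS = tuple(float(x) for x in np.logspace(-3, 2, 6))
_ALPHAS = (0.1, 0.5, 0.9)

DEFAULT_GRIDS: dict[str, dict[str, tuple]] = {
    "lda-enet": {"clf__lam": _LAMBDAS, "clf__alpha": _ALPHAS},
    "logistic-enet": {"clf__C": tuple(1.0 / l for l in _LAMBDAS), "clf__l1_ratio": _ALPHAS},
    "xgboost": {
        "clf__max_depth": (2, 3),
        "clf__learning_rate": (0.1, 0.3),
        "clf__n_estimators": (50, 200),
    },
}


class ElasticNetLDA(BaseEstimator, ClassifierMixin):
    """Two-class LDA with an elastic-net penalty via optimal scoring.

    Regresses a +-1 class indicator with the elastic-net objective
    ``1/(2n) ||y - Xb||^2 + lam (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2)``;
    a test point is scored by its regression value relative to the midpoint
    of the training class means, squashed through a logistic link so the
    score reads as a probability of the positive class.
    """

    def __init__(self, lam: float = 0.01, alpha: float = 0.5):
        self.lam = lam
        self.alpha = alpha

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ElasticNetLDA is strictly two-class")
        t = np.where(y == self.classes_[1], 1.0, -1.0)
        self._enet = ElasticNet(alpha=self.lam, l1_ratio=self.alpha, max_iter=5000)
        self._enet.fit(X, t)
        s = self._enet.predict(X)
        m_neg = s[t < 0].mean()
        m_pos = s[t > 0].mean()
        self.midpoint_ = 0.5 * (m_neg + m_pos)
        spread = 0.5 * (s[t < 0].std() + s[t > 0].std())
        self.scale_ = spread if spread > 0 else max(abs(m_pos - m_neg) / 4.0, 1e-12)
        self.coef_ = self._enet.coef_
        return self

    def decision_function(self, X):
        return self._enet.predict(np.asarray(X)) - self.midpoint_

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X) / self.scale_))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


@dataclass
class ModelSpec:
    """One model family plus its hyperparameter grid and inner-CV settings."""

    family: str = "logistic-enet"
    param_grid: dict[str, tuple] | None = None
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}, got {self.family!r}")


def _base_pipeline(family: str, seed: int) -> Pipeline:
    if family == "lda-enet":
        clf: Any = ElasticNetLDA()
    elif family == "logistic-enet":
        clf = LogisticRegression(
            solver="saga", l1_ratio=0.5, C=1.0,
            max_iter=5000, tol=1e-4, random_state=seed,
        )
    elif family == "xgboost":
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1,
            tree_method="hist", n_jobs=1, random_state=seed,
            eval_metric="logloss", verbosity=0,
        )
    else:
        raise ValueError(f"unknown family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def make_model(
    family: str,
    param_grid: dict[str, tuple] | None = None,
    inner_cv_folds: int = 5,
    seed: int = 0,
):
    """Build the classifier for one family.

    With a grid of more than one candidate the returned estimator is a
    GridSearchCV over a standardize+classify pipeline (inner stratified
    five-fold CV); a single-candidate grid skips the search.
    """
    if param_grid is None:
        param_grid = DEFAULT_GRIDS[family]
    pipe = _base_pipeline(family, seed)
    n_cand = int(np.prod([len(v) for v in param_grid.values()])) if param_grid else 1
    if n_cand <= 1:
        if param_grid:
            pipe.set_params(**{k: v[0] for k, v in param_grid.items()})
        return pipe
    inner = StratifiedKFold(n_splits=inner_cv_folds, shuffle=True, random_state=seed)
    return GridSearchCV(pipe, dict(param_grid), cv=inner, scoring="accuracy", n_jobs=1)


def model_from_spec(spec: ModelSpec):
    return make_model(spec.family, spec.param_grid, spec.inner_cv_folds, spec.seed)


def fit_predict(model, X_train, y_train, X_test) -> np.ndarray:
    """Fit on the training set (inner grid search included) and return the
    probability of the positive class for each test item."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    if isinstance(model, ModelSpec):
        model = model_from_spec(model)
    est = clone(model)
    est.fit(np.asarray(X_train), y_train)
    proba = est.predict_proba(np.asarray(X_test))
    classes = est.classes_ if hasattr(est, "classes_") else est.best_estimator_.classes_
    pos_col = int(np.argmax(classes))
    return proba[:, pos_col]


@dataclass
class EvaluationResult:
    """Pooled out-of-fold LOOCV evaluation of one task/model."""

    y_true: np.ndarray
    scores: np.ndarray
    y_pred: np.ndarray
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)  # type: ignore[assignment]

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)."""
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("counts must be non-negative with positive total")
    if tp + fn == 0:
        raise ValueError("no positive items: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative items: specificity undefined")
    return {
        "accuracy": (tp + tn) / (tp + fp + tn + fn),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve = P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def loocv(model, X, y, threshold: float = 0.5) -> EvaluationResult:
    """Leave-one-out CV: N fits, each excluding one lesion; the held-out label
    is never visible to fitting or the inner grid search."""
    X = np.asarray(X)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    if n < 4 or len(classes) != 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("need N >= 4 with at least 2 items per class")
    if isinstance(model, ModelSpec):
        model = model_from_spec(model)
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        scores[i] = fit_predict(model, X[mask], y[mask], X[i : i + 1])[0]
    pos = classes[1]
    y_bin = (y == pos).astype(int)
    y_pred = (scores >= threshold).astype(int)
    tp = int(((y_pred == 1) & (y_bin == 1)).sum())
    fp = int(((y_pred == 1) & (y_bin == 0)).sum())
    tn = int(((y_pred == 0) & (y_bin == 0)).sum())
    fn = int(((y_pred == 0) & (y_bin == 1)).sum())
    m = metrics(tp, fp, tn, fn)
    fpr, tpr, _ = roc_curve(y_bin, scores)
    return EvaluationResult(
        y_true=y_bin, scores=scores, y_pred=y_pred, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=m["accuracy"], sensitivity=m["sensitivity"],
        specificity=m["specificity"], auc=auc(scores, y_bin), roc=(fpr, tpr),
    )
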