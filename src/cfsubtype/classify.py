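"""L2-penalized logistic subtype classifier with ROC/AUC and DeLong CIs.

The model is scikit-learn logistic regression with the L2 penalty at
C = 0.1 and otherwise default hyperparameters; no feature standardization
is applied by default.  Cross-validation pools every held-out score into a
single ROC (for leave-one-out this is the only coherent reading) and the
AUC interval is the DeLong structural-components normal interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .types import ValidationError

DEFAULT_C = 0.1


@dataclass
class ClassifierModel:
    weights: np.ndarray
    intercept: float
    C: float
    classes: tuple
    feature_names: tuple | None = None
    mean: np.ndarray | None = None  # set when standardized
    scale: np.ndarray | None = None


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        assert self.ci_low <= self.auc + 1e-12
        assert self.ci_high >= self.auc - 1e-12


def _as_binary(labels) -> tuple[np.ndarray, tuple]:
    y = np.asarray(labels)
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {classes}")
    return (y == classes[1]).astype(int), classes


def fit(
    features,
    labels,
    C: float = DEFAULT_C,
    standardize: bool = False,
    tol: float = 1e-6,
) -> ClassifierModel:
    """Fit the L2-penalized logistic model (positive = lexicographically
    larger class)."""
    X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite feature values")
    y, classes = _as_binary(labels)
    mean = scale = None
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - mean) / scale
    # l1_ratio=0 is the L2 penalty (sklearn >=1.8 deprecates penalty="l2")
    clf = LogisticRegression(l1_ratio=0, C=C, tol=tol, max_iter=10_000)
    clf.fit(X, y)
    names = tuple(features.columns) if isinstance(features, pd.DataFrame) else None
    return ClassifierModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        C=C,
        classes=classes,
        feature_names=names,
        mean=mean,
        scale=scale,
    )


def predict_scores(model: ClassifierModel, features) -> np.ndarray:
    """Probability of the positive (second) class."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.weights):
        raise ValidationError(
            f"feature dimension {X.shape} does not match model "
            f"({len(model.weights)} features)"
        )
    if model.mean is not None:
        X = (X - model.mean) / model.scale
    z = X @ model.weights + model.intercept
    return 1.0 / (1.0 + np.exp(-z))


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative),
    ties counted half."""
    y, _ = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_variance(scores, labels) -> float:
    y, _ = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    v10, v01 = _delong_components(s, y)
    if len(v10) < 2 or len(v01) < 2:
        raise ValidationError("DeLong variance requires >= 2 samples per class")
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation DeLong interval for the AUC, clipped to [0, 1]."""
    a = auc(scores, labels)
    se = float(np.sqrt(delong_variance(scores, labels)))
    z = norm.ppf(0.5 + level / 2)
    return (max(0.0, a - z * se), min(1.0, a + z * se))


def cross_validate(
    features,
    labels,
    scheme: str = "loocv",
    n_splits: int = 10,
    seed: int = 0,
    C: float = DEFAULT_C,
    standardize: bool = False,
    level: float = 0.95,
) -> RocResult:
    """Pooled-ROC cross-validation.

    Every sample is scored exactly once by a model never trained on it;
    the held-out scores are pooled into one ROC and the AUC gets a DeLong
    interval.  ``scheme`` is ``"loocv"`` or ``"kfold"`` (stratified,
    shuffled with ``seed``).
    """
    X = np.asarray(features, dtype=float)
    y_raw = np.asarray(labels)
    y, classes = _as_binary(y_raw)
    n = len(y)
    scores = np.full(n, np.nan)
    if scheme == "loocv":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif scheme == "kfold":
        if min((y == 0).sum(), (y == 1).sum()) < n_splits:
            raise ValidationError("too few samples per class for k-fold")
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")
    for train, test in folds:
        if len(np.unique(y[train])) < 2:
            raise ValidationError("training fold lost a class; cannot score")
        model = fit(X[train], y[train], C=C, standardize=standardize)
        scores[test] = predict_scores(model, X[test])
    a = auc(scores, y)
    lo, hi = delong_ci(scores, y, level=level)
    return RocResult(auc=a, ci_low=lo, ci_high=hi, scores=scores, labels=y_raw)
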