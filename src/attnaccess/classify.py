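"""Two-class linear discriminant on per-trial averaged features.

The discriminant direction is w = (S + lambda*I)^-1 (mu_att - mu_non)
with S the pooled within-class covariance.  The ridge term lambda is zero
unless S is singular or near-singular (condition number > 1e8), in which
case lambda = eps * trace(S) / d (eps = 1e-3) -- necessary in the
small-sample windowed analysis where ten-dimensional features are fitted
from six trials.  Class priors are equal (the protocol is balanced), so
the decision threshold is the midpoint of the projected class means, with
the orientation fixed so the attention class projects higher.

Performance is estimated with stratified k-fold cross-validation (k = 4):
accuracy is pooled correct/total over held-out folds and the AUC is the
mid-rank Mann-Whitney statistic of the pooled held-out projection scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .core import ATTENTION, NON_ATTENTION

RIDGE_EPS = 1e-3
COND_LIMIT = 1e8


@dataclass
class FeatureVector:
    """One trial's averaged features with its class label."""

    values: np.ndarray
    label: str
    subject_id: str = ""
    session_index: int = 0
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.label not in (ATTENTION, NON_ATTENTION):
            raise ValueError(f"label must be attention/non_attention, got {self.label!r}")


@dataclass
class LdaModel:
    weights: np.ndarray
    threshold: float
    ridge: float
    proj_mean_att: float
    proj_mean_non: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.any(self.weights):
            raise ValueError("weight vector must be non-zero")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def dim(self) -> int:
        return self.weights.shape[0]


def _stack(train: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([fv.values for fv in train])
    y = np.array([fv.label for fv in train])
    return X, y


def fit_lda(train: Sequence[FeatureVector]) -> LdaModel:
    """Fit the pooled-covariance linear discriminant.

    Raises when a class is missing or when the input is degenerate (zero
    variance and identical class means: nothing separates the classes).
    """
    X, y = _stack(train)
    Xa, Xn = X[y == ATTENTION], X[y == NON_ATTENTION]
    if len(Xa) == 0 or len(Xn) == 0:
        raise ValueError("both classes must be present in the training data")
    d = X.shape[1]
    mu_a, mu_n = Xa.mean(axis=0), Xn.mean(axis=0)
    diff = mu_a - mu_n
    dev_a = Xa - mu_a
    dev_n = Xn - mu_n
    dof = max(len(X) - 2, 1)
    cov = (dev_a.T @ dev_a + dev_n.T @ dev_n) / dof
    trace = float(np.trace(cov))
    if trace == 0.0:
        if not np.any(diff):
            raise ValueError(
                "degenerate training data: zero variance and identical class means"
            )
        ridge = 1.0  # covariance carries no information; use the mean difference
    else:
        cond = np.linalg.cond(cov)
        ridge = RIDGE_EPS * trace / d if (not np.isfinite(cond) or cond > COND_LIMIT) else 0.0
    w = np.linalg.solve(cov + ridge * np.eye(d), diff)
    if not np.any(w):
        raise ValueError("inseparable training data: identical class means")
    pa, pn = float(w @ mu_a), float(w @ mu_n)
    if pa < pn:  # orient so the attention class projects higher
        w, pa, pn = -w, -pa, -pn
    return LdaModel(
        weights=w,
        threshold=0.5 * (pa + pn),
        ridge=ridge,
        proj_mean_att=pa,
        proj_mean_non=pn,
    )


def project(model: LdaModel, values: np.ndarray | FeatureVector) -> float:
    """Projection score of one feature vector onto the discriminant axis."""
    v = values.values if isinstance(values, FeatureVector) else np.atleast_1d(values)
    if v.shape[0] != model.dim:
        raise ValueError(f"dimension mismatch: model {model.dim}, vector {v.shape[0]}")
    return float(model.weights @ np.asarray(v, dtype=float))


def predict(model: LdaModel, values: np.ndarray | FeatureVector) -> str:
    """attention when the score exceeds the threshold, else non_attention."""
    return ATTENTION if project(model, values) > model.threshold else NON_ATTENTION


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (mid-ranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == ATTENTION
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both labels must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CvResult:
    accuracy_pct: float
    auc: float
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    predictions: np.ndarray = field(repr=False)


def kfold_cv(dataset: Sequence[FeatureVector], k: int = 4, seed: int = 0) -> CvResult:
    """Stratified k-fold cross-validation of the discriminant.

    Accuracy is pooled correct/total over all held-out folds; AUC comes
    from the pooled held-out projection scores.  Fold assignment depends
    only on (seed, dataset order).
    """
    X, y = _stack(dataset)
    for label in (ATTENTION, NON_ATTENTION):
        if int((y == label).sum()) < k:
            raise ValueError(f"need >= {k} vectors per class for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        model = fit_lda([FeatureVector(X[i], y[i]) for i in train_idx])
        for i in test_idx:
            scores[i] = project(model, X[i])
            preds[i] = ATTENTION if scores[i] > model.threshold else NON_ATTENTION
    accuracy = 100.0 * float((preds == y).mean())
    return CvResult(
        accuracy_pct=accuracy,
        auc=rank_auc(scores, y),
        scores=scores,
        labels=y,
        predictions=preds.astype(str),
    )


def roc_curve(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (FPR, TPR) from a threshold sweep, plus the rank AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both labels must be present")
    fpr, tpr, _ = _sk_roc_curve(labels == ATTENTION, scores)
    return fpr, tpr, rank_auc(scores, labels)
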