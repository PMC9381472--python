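"""Logistic lateralization with leave-one-out cross-validation.

Left-sided epilepsy (LTLE) is coded 1 (positive), right-sided (RTLE) 0.
At cohorts of a couple of dozen subjects with near-separable asymmetry
features, unpenalized maximum likelihood diverges, so the default fit is
L2-penalized (ridge) logistic regression with C = 1 (inverse penalty
strength); pass ``penalty=None`` for plain maximum likelihood.

LOOCV refits the model n times, each time predicting the held-out
subject; the pooled held-out probabilities give one ROC / AUC / MSE per
cohort.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .types import LateralizationResult

__all__ = [
    "fit_logistic",
    "loocv_probabilities",
    "roc_auc",
    "probability_mse",
    "accuracy_summary",
    "evaluate_loocv",
]


def _as_2d(features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("features must be a (n_subjects, n_features) table")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing/non-finite values")
    return X


def fit_logistic(
    features,
    labels,
    penalty: str | None = "l2",
    C: float = 1.0,
) -> LogisticRegression:
    """Fit a binary logistic model (intercept included, deterministic).

    Returns the fitted scikit-learn estimator; coefficients are in
    ``.coef_`` and ``.intercept_``.
    """
    X = _as_2d(features)
    y = np.asarray(labels, dtype=int)
    if y.shape != (X.shape[0],):
        raise ValueError("labels length must match number of subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("need samples of both classes to fit")
    if penalty == "l2":
        eff_C = C
    elif penalty is None or penalty == "none":
        eff_C = np.inf  # plain maximum likelihood
    else:
        raise ValueError(f"unsupported penalty {penalty!r}")
    model = LogisticRegression(C=eff_C, solver="lbfgs", max_iter=5000)
    model.fit(X, y)
    return model


def loocv_probabilities(
    features, labels, penalty: str | None = "l2", C: float = 1.0
) -> np.ndarray:
    """Held-out positive-class probability for every subject.

    For each subject the model is refit on the remaining n-1; output order
    matches input order. Raises if any training fold collapses to a single
    class, naming the held-out subject.
    """
    X = _as_2d(features)
    y = np.asarray(labels, dtype=int)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    probs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                f"training fold for held-out subject {i} has one class only"
            )
        model = fit_logistic(X[tr], y[tr], penalty=penalty, C=C)
        pos = list(model.classes_).index(1)
        probs[i] = model.predict_proba(X[i:i + 1])[0, pos]
    return probs


def roc_auc(probabilities, labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) formula.

    Equals the probability that a random positive outranks a random
    negative, ties counted one half; identical to the trapezoidal area
    under the empirical ROC.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def probability_mse(probabilities, labels) -> float:
    """Mean squared error between labels and predicted probabilities."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    return float(np.mean((y - p) ** 2))


def accuracy_summary(
    calls: Sequence[str], truth: Sequence[str]
) -> tuple[int, int, float]:
    """(n_correct, n_total, percent to two decimals) of hard calls."""
    if len(calls) != len(truth):
        raise ValueError("calls and truth must have equal length")
    if len(calls) == 0:
        raise ValueError("empty input")
    n_correct = sum(c == t for c, t in zip(calls, truth))
    n_total = len(calls)
    return n_correct, n_total, round(100.0 * n_correct / n_total, 2)


def evaluate_loocv(
    features,
    labels,
    model_name: str = "model",
    penalty: str | None = "l2",
    C: float = 1.0,
) -> LateralizationResult:
    """Full LOOCV evaluation: probabilities, hard calls, ROC, AUC, MSE.

    Hard calls use a 0.5 threshold; a probability of exactly 0.5 is an
    undetermined call ("U"), counted incorrect.
    """
    y = np.asarray(labels, dtype=int)
    probs = loocv_probabilities(features, y, penalty=penalty, C=C)
    calls = ["L" if p > 0.5 else ("R" if p < 0.5 else "U") for p in probs]
    truth = ["L" if t == 1 else "R" for t in y]
    n_correct, n_total, _ = accuracy_summary(calls, truth)
    tp = sum(c == "L" and t == "L" for c, t in zip(calls, truth))
    tn = sum(c == "R" and t == "R" for c, t in zip(calls, truth))
    fp = sum(c == "L" and t == "R" for c, t in zip(calls, truth))
    fn = n_total - tp - tn - fp
    fpr, tpr, _ = roc_curve(y, probs)
    return LateralizationResult(
        model_name=model_name,
        labels=y,
        probabilities=probs,
        calls=calls,
        auc=roc_auc(probs, y),
        mse=probability_mse(probs, y),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        n_correct=n_correct,
        n_total=n_total,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )
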