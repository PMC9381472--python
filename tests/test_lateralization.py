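"""Logistic LOOCV lateralization, AUC/MSE metrics, and their oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from hippolat.lateralization import (
    accuracy_summary,
    evaluate_loocv,
    fit_logistic,
    loocv_probabilities,
    probability_mse,
    roc_auc,
)


def auc_pairwise_oracle(probs, labels):
    """Brute force: count positive>negative pairs, ties worth one half."""
    probs, labels = np.asarray(probs), np.asarray(labels)
    pos, neg = probs[labels == 1], probs[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_trivial_cases():
    assert roc_auc([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0
    assert roc_auc([0.4, 0.4], [1, 0]) == 0.5


@given(
    st.lists(st.integers(0, 4), min_size=2, max_size=8).filter(
        lambda xs: len(set(xs)) > 1
    ),
    st.integers(0, 10**6),
)
@settings(max_examples=200, deadline=None)
def test_auc_matches_pairwise_oracle(quantized, seed):
    rng = np.random.default_rng(seed)
    n = len(quantized)
    labels = np.zeros(n, int)
    labels[rng.choice(n, rng.integers(1, n), replace=False)] = 1
    if labels.sum() in (0, n):
        labels[0], labels[-1] = 0, 1
    probs = np.asarray(quantized) / 4.0  # coarse grid induces ties
    assert roc_auc(probs, labels) == pytest.approx(
        auc_pairwise_oracle(probs, labels), abs=1e-12
    )
    assert roc_auc(probs, labels) == pytest.approx(
        roc_auc_score(labels, probs), abs=1e-12
    )


def test_auc_label_flip_symmetry():
    rng = np.random.default_rng(3)
    probs = rng.random(20)
    labels = rng.integers(0, 2, 20)
    labels[:2] = [0, 1]
    assert roc_auc(probs, labels) == pytest.approx(
        roc_auc(-probs, 1 - labels), abs=1e-12
    )


def test_large_sample_auc_matches_binormal_closed_form():
    # simulate->rank path against Phi(|mu1-mu0| / sqrt(s1^2+s0^2))
    rng = np.random.default_rng(11)
    n = 10**5
    x1 = rng.normal(0.38, 0.81, n)
    x0 = rng.normal(-1.11, 1.28, n)
    vals = np.concatenate([x1, x0])
    labels = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    expected = norm.cdf((0.38 + 1.11) / np.hypot(0.81, 1.28))
    assert roc_auc(vals, labels) == pytest.approx(expected, abs=0.01)


def test_probability_mse_hand_values():
    assert probability_mse([1.0, 0.0], [1, 0]) == 0.0
    assert probability_mse([0.5, 0.5], [1, 0]) == 0.25
    assert probability_mse([0.9, 0.6, 0.2], [1, 1, 0]) == pytest.approx(0.07)
    with pytest.raises(ValueError):
        probability_mse([], [])


def test_accuracy_summary_values():
    calls = ["L"] * 44 + ["R"] * 2
    truth = ["L"] * 46
    assert accuracy_summary(calls, truth) == (44, 46, 95.65)
    calls = ["L"] * 39 + ["R"] * 7
    assert accuracy_summary(calls, truth)[2] == pytest.approx(84.78, abs=0.005)
    assert accuracy_summary(["R", "R"], ["L", "L"]) == (0, 2, 0.0)
    with pytest.raises(ValueError):
        accuracy_summary(["L"], ["L", "R"])


def test_fit_logistic_separable_and_uninformative():
    X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    y = np.array([0, 0, 1, 1])
    model = fit_logistic(X, y)
    p = model.predict_proba(X)[:, 1]
    assert np.all((p > 0.5) == (y == 1))
    # constant feature: coefficient shrinks to ~0, probs ~ prevalence
    Xc = np.ones((10, 1))
    yc = np.array([1] * 7 + [0] * 3)
    mc = fit_logistic(Xc, yc)
    assert abs(mc.coef_[0, 0]) < 1e-2
    assert mc.predict_proba(Xc)[0, 1] == pytest.approx(0.7, abs=0.01)
    with pytest.raises(ValueError):
        fit_logistic(X, np.ones(4, int))


def test_logistic_parameter_recovery_unpenalized():
    rng = np.random.default_rng(5)
    n = 10**4
    X = rng.normal(0, 1, (n, 2))
    logits = 0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    model = fit_logistic(X, y, penalty=None)
    assert model.intercept_[0] == pytest.approx(0.5, rel=0.10)
    assert model.coef_[0, 0] == pytest.approx(1.2, rel=0.05)
    assert model.coef_[0, 1] == pytest.approx(-0.8, rel=0.05)


def test_loocv_basic_contracts():
    X = np.array([[0.0], [0.1], [1.0], [0.9]])
    y = np.array([0, 0, 1, 1])
    # unpenalized fit: a feature that equals the label must put every
    # held-out subject on the correct side of 0.5
    p = loocv_probabilities(X, y, penalty=None)
    assert np.all(p[y == 1] > 0.5) and np.all(p[y == 0] < 0.5)
    # order equivariance
    perm = np.array([2, 0, 3, 1])
    p2 = loocv_probabilities(X[perm], y[perm], penalty=None)
    assert np.allclose(p2, p[perm], atol=1e-8)
    with pytest.raises(ValueError, match="subject 0"):
        loocv_probabilities(np.array([[0.0], [1.0], [2.0]]), np.array([1, 0, 0]))
    with pytest.raises(ValueError):
        loocv_probabilities(X[:2], y[:2])


def test_evaluate_loocv_bundle_consistency():
    rng = np.random.default_rng(9)
    X = np.concatenate([rng.normal(1, 1, (14, 1)), rng.normal(-1, 1, (10, 1))])
    y = np.array([1] * 14 + [0] * 10)
    res = evaluate_loocv(X, y, model_name="T2")
    assert np.all((res.probabilities >= 0) & (res.probabilities <= 1))
    assert 0 <= res.auc <= 1
    assert res.mse == pytest.approx(
        np.mean((y - res.probabilities) ** 2), abs=1e-12
    )
    c = res.confusion
    assert c["tp"] + c["fp"] + c["tn"] + c["fn"] == res.n_total == 24
    assert res.n_correct == c["tp"] + c["tn"]


def test_hemisphere_swap_flips_calls_and_preserves_auc():
    # mirroring left/right negates AIs, swaps class labels, and must flip
    # every hard call while leaving discrimination unchanged
    rng = np.random.default_rng(21)
    X = np.concatenate([rng.normal(0.8, 0.8, (14, 1)), rng.normal(-0.9, 1.2, (10, 1))])
    y = np.array([1] * 14 + [0] * 10)
    res = evaluate_loocv(X, y)
    res_sw = evaluate_loocv(-X, 1 - y)
    assert res_sw.auc == pytest.approx(res.auc, abs=1e-9)
    flip = {"L": "R", "R": "L", "U": "U"}
    assert res_sw.calls == [flip[c] for c in res.calls]
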