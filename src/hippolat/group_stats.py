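"""Nonparametric paired and two-sample tests for group comparisons.

Thin wrappers over scipy.stats with an explicit exact-vs-approximate
policy: the exact null (full enumeration) for small tie-free samples,
the normal approximation with tie and continuity corrections otherwise.
All p values are two-sided; alpha = 0.05 by convention, no
multiple-testing correction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["wilcoxon_signed_rank", "mann_whitney_u"]

# Enumeration is cheap up to 2^12 sign patterns / C(12, k) arrangements.
_EXACT_N_MAX = 12


def wilcoxon_signed_rank(
    paired_a, paired_b, zero_method: str = "wilcox"
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking (classical convention);
    ``zero_method="pratt"`` keeps them in the ranking instead. The null
    distribution is exact (all 2^n sign assignments) for n <= 12, else a
    normal approximation with continuity correction.

    Returns (W statistic, p value). Raises when every difference is zero.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    d = a - b
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; no information")
    nz = d[d != 0]
    method = "exact" if nz.size <= _EXACT_N_MAX else "approx"
    res = stats.wilcoxon(
        a, b, zero_method=zero_method, correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on two independent samples.

    Exact null for combined n <= 12, normal approximation with tie and
    continuity corrections otherwise. Returns (U for group a, p value).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if a.size + b.size <= _EXACT_N_MAX else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
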