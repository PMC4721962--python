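"""Nonparametric paired and two-sample tests.

Thin, conventions-fixing wrappers around scipy's Wilcoxon signed-rank and
rank-sum (Mann-Whitney) machinery.  Exact null distributions are used for
small samples; above ``EXACT_N_MAX`` observations the normal approximation
with continuity correction is used.  For small two-sample problems that
contain ties *across* the groups, scipy's exact method does not condition on
the tie pattern, so the permutation null is enumerated directly instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "signed_rank_test",
    "rank_sum_test",
    "correct_pvalues",
]

#: largest per-sample n for which the exact null distribution is used
EXACT_N_MAX = 25

#: largest pooled n for which ties trigger full enumeration
_ENUM_TOTAL_MAX = 14
_SIGNED_ENUM_MAX = 18


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n: int
    method: str
    alternative: str


def signed_rank_test(
    x,
    y=None,
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples (or precomputed differences).

    ``alternative='greater'`` tests for x > y (positive differences).  Pairs
    with zero difference are dropped (Wilcoxon's convention).  If every
    difference is zero the test is degenerate and p = 1 is returned with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if y is not None and len(x) != len(d):
        raise ValueError("paired samples must have equal length")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; test is degenerate (p = 1)")
        return TestResult(0.0, 1.0, 0, "degenerate", alternative)

    n = nonzero.size
    has_tied_abs = np.unique(np.abs(nonzero)).size < n
    if has_tied_abs and n <= _SIGNED_ENUM_MAX and alternative != "two-sided":
        # tied |differences|: scipy's exact null ignores the tie pattern, so
        # enumerate the 2^n sign assignments conditioning on the observed ranks
        p = _signed_rank_enumerate(nonzero, alternative)
        ranks = sps.rankdata(np.abs(nonzero))
        w = float(ranks[nonzero > 0].sum())
        return TestResult(w, float(p), n, "enumeration", alternative)
    if n <= EXACT_N_MAX and not has_tied_abs:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(
        nonzero,
        alternative=alternative,
        method=method,
        correction=(method == "approx"),
        zero_method="wilcox",
    )
    return TestResult(float(res.statistic), float(res.pvalue), n, method, alternative)


def _signed_rank_enumerate(diffs: np.ndarray, alternative: str) -> float:
    """Exact signed-rank p by enumerating sign assignments (handles tied ranks)."""
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    # all 2^n sign patterns as a bit matrix
    codes = np.arange(2**n, dtype=np.uint32)
    signs = (codes[:, None] >> np.arange(n)) & 1
    w = signs @ ranks
    if alternative == "greater":
        return float(np.count_nonzero(w >= w_obs - 1e-12) / 2**n)
    return float(np.count_nonzero(w <= w_obs + 1e-12) / 2**n)


def _ranksum_enumerate(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Exact permutation p for the rank-sum statistic, conditioning on ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    total = math.comb(len(pooled), n1)
    count = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        if alternative == "greater":
            count += w >= w_obs - 1e-12
        elif alternative == "less":
            count += w <= w_obs + 1e-12
        else:
            raise ValueError("enumeration supports one-sided alternatives only")
    return count / total


def rank_sum_test(a, b, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum test of two independent samples.

    ``alternative='greater'`` tests whether values in ``a`` tend to exceed
    those in ``b``.  Uses the exact null for samples of at most
    ``EXACT_N_MAX`` per group; small samples with ties spanning the two
    groups are handled by enumerating the permutation null.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(a.size, b.size) <= EXACT_N_MAX
    if small and has_ties and a.size + b.size <= _ENUM_TOTAL_MAX and alternative != "two-sided":
        p = _ranksum_enumerate(a, b, alternative)
        w = sps.rankdata(pooled)[: a.size].sum()
        return TestResult(float(w), float(p), a.size + b.size, "enumeration", alternative)

    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), a.size + b.size, method, alternative)


def correct_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Family-wise error correction across a family of tests.

    ``method`` is ``'bonferroni'`` or ``'holm'``.  Returns adjusted p-values
    clipped to 1.
    """
    from statsmodels.stats.multitest import multipletests

    pvalues = np.asarray(pvalues, dtype=float)
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"unknown correction method {method!r}")
    _, adj, _, _ = multipletests(pvalues, method=method)
    return adj
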