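"""Shared statistical tests used across the pipeline.

Thin, contract-enforcing wrappers around SciPy with the conventions used
throughout the analysis: two-sided alternatives everywhere (directionality
is handled by callers, e.g. the defect labels), exact Mann-Whitney U
p-values for small samples, and mean +/- SE reported alongside the rank
tests because group summaries are displayed that way.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int = 0
    adjustment: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def mean_se(x) -> tuple[float, float]:
    """Mean and standard error of the mean (SE 0 for a single value)."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    se = arr.std(ddof=1) / sqrt(arr.size) if arr.size > 1 else 0.0
    return float(arr.mean()), float(se)


#: total sample size up to which the exact Mann-Whitney null is used
MWU_EXACT_MAX_N = 12


def mwu_test(a, b, alternative: str = "two-sided") -> TestResult:
    """Two-sided Mann-Whitney U rank-sum test.

    Uses the exact permutation null for small samples without ties
    (n_a + n_b <= 12) and the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mwu_test requires non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= MWU_EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method=f"mwu-{method}",
        n_a=int(a.size),
        n_b=int(b.size),
    )


def chisq_gof(observed, expected) -> TestResult:
    """Pearson goodness-of-fit chi-square test, df = cells - 1."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.size < 2:
        raise ValueError("goodness-of-fit test needs at least 2 cells")
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    # scipy requires matching totals; rescale expected proportions
    expected = expected * observed.sum() / expected.sum()
    res = stats.chisquare(observed, expected)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="chisq-gof",
        n_a=int(observed.sum()),
    )


def chisq_contingency_2x2(table) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table (no Yates correction)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="chisq-2x2",
        n_a=int(table.sum()),
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums the probabilities of all tables with the same
    margins whose point probability does not exceed the observed one.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0):
        raise ValueError("table cells must be non-negative")
    res = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="fisher-exact",
        n_a=int(table.sum()),
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    mult = len(p) if m is None else m
    if mult < len(p):
        raise ValueError("Bonferroni multiplier smaller than number of tests")
    return np.minimum(1.0, p * mult)


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1; invariant under
    input permutation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(1.0, q_sorted)
    return q
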