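"""Hypothesis tests behind the DMR caller.

Each tested unit (a CpG, or a multi-CpG region summarised by per-sample
average depth) is first routed by Bartlett's homogeneity-of-variance test:
equal variances (Bartlett p > alpha) send it to the parametric Student's
paired t-test; unequal variances send it to the non-parametric Wilcoxon
rank-sum test. Two-sided p-values throughout.

The rank-sum branch is exact for combined n <= 20 — including ties, via a
dynamic program over the midrank multiset (no closed form or library routine
covers the tied exact case) — and uses the normal approximation with tie
correction above that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestChoice",
    "PARAMETRIC",
    "NONPARAMETRIC",
    "route_test",
    "site_test",
    "paired_t_pvalue",
    "rank_sum_pvalue",
    "rank_sum_exact_null",
    "site_tests_matrix",
    "bh_adjust",
]

PARAMETRIC = "parametric-paired-t"
NONPARAMETRIC = "nonparametric-wilcoxon-rank-sum"

_TINY_P = float(np.finfo(np.float64).tiny)


@dataclass(frozen=True)
class TestChoice:
    """Outcome of Bartlett routing for one tested unit."""

    choice: str  # PARAMETRIC or NONPARAMETRIC
    bartlett_stat: float
    bartlett_p: float


def _bartlett_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Bartlett statistic/p for two groups, with degenerate handling.

    Both variances zero: the homoscedasticity premise holds trivially;
    report statistic 0, p = 1. Exactly one zero variance: maximal
    heterogeneity; statistic inf, p = 0.
    """
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va == 0.0 and vb == 0.0:
        return 0.0, 1.0
    if va == 0.0 or vb == 0.0:
        return float("inf"), 0.0
    stat, p = sps.bartlett(a, b)
    return float(stat), float(p)


def route_test(values_a, values_b, bartlett_alpha: float = 0.05) -> TestChoice:
    """Route one tested unit to the parametric or non-parametric branch."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    stat, p = _bartlett_two_sample(a, b)
    choice = PARAMETRIC if p > bartlett_alpha else NONPARAMETRIC
    return TestChoice(choice, stat, p)


def paired_t_pvalue(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t on within-pair differences → (t, p).

    Zero-variance differences: all-zero → (0, 1); constant non-zero → the
    smallest representable p with a warning (the evidence is off the t scale).
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = float(np.std(d, ddof=1))
    m = float(np.mean(d))
    if sd == 0.0:
        if m == 0.0:
            return 0.0, 1.0
        warnings.warn("zero-variance paired differences with nonzero mean")
        return float(np.sign(m)) * float("inf"), _TINY_P
    t = m / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return float(t), min(p, 1.0)


def rank_sum_exact_null(scaled_ranks: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the group-A rank sum under label exchange.

    ``scaled_ranks`` are midranks times 2 (integers, so ties cost nothing).
    Returns (support, counts): the achievable scaled rank sums for a size-n1
    subset and the number of subsets attaining each, via a subset-sum dynamic
    program — O(N * n1 * total).
    """
    r = np.asarray(scaled_ranks, dtype=np.int64)
    total = int(r.sum())
    # ways[k, s] = number of size-k subsets of processed items with scaled sum s
    ways = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    ways[0, 0] = 1.0
    for v in r:
        v = int(v)
        ways[1:, v:] += ways[:-1, : total + 1 - v]
    counts = ways[n1]
    support = np.nonzero(counts)[0]
    return support, counts[support]


def rank_sum_pvalue(values_a, values_b, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test → (centered statistic, p).

    The statistic is W_A − E[W_A], W_A the midrank sum of group A. For
    combined n <= ``exact_max_n`` the p-value is exact over all
    C(N, n1) label assignments (ties handled by midranks in the DP); above,
    the normal approximation with tie correction (no continuity correction,
    matching the large-sample permutation limit).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_a = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    stat = w_a - mu
    if n1 + n2 <= exact_max_n:
        scaled = np.rint(2 * ranks).astype(np.int64)
        support, counts = rank_sum_exact_null(scaled, n1)
        obs = abs(2 * w_a - 2 * mu)
        extreme = counts[np.abs(support - 2 * mu) >= obs - 1e-9].sum()
        p = float(extreme) / comb(n1 + n2, n1)
        return stat, min(p, 1.0)
    # tie-corrected normal approximation
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0.0:
        return stat, 1.0
    z = stat / np.sqrt(var)
    return stat, min(2.0 * float(sps.norm.sf(abs(z))), 1.0)


def site_test(depths_a, depths_b, choice: TestChoice) -> float:
    """Two-sided p-value for one tested unit on pair-aligned group vectors."""
    a = np.asarray(depths_a, dtype=float)
    b = np.asarray(depths_b, dtype=float)
    if choice.choice == PARAMETRIC:
        if a.size != b.size:
            raise ValueError("paired t requires equal-length pair-aligned vectors")
        _, p = paired_t_pvalue(a - b)
    else:
        _, p = rank_sum_pvalue(a, b)
    return p


# ---------------------------------------------------------------------------
# vectorised genome-wide scan


def _bartlett_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-group Bartlett statistic and p (closed form, k = 2)."""
    na, nb = a.shape[1], b.shape[1]
    va = np.var(a, axis=1, ddof=1)
    vb = np.var(b, axis=1, ddof=1)
    n = na + nb
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (n - 2)
        t = (n - 2) * np.log(sp2) - (na - 1) * np.log(va) - (nb - 1) * np.log(vb)
    c = 1.0 + (1.0 / (na - 1) + 1.0 / (nb - 1) - 1.0 / (n - 2)) / 3.0
    stat = t / c
    p = sps.chi2.sf(stat, 1)
    both_zero = (va == 0) & (vb == 0)
    one_zero = (va == 0) ^ (vb == 0)
    stat = np.where(both_zero, 0.0, stat)
    p = np.where(both_zero, 1.0, p)
    stat = np.where(one_zero, np.inf, stat)
    p = np.where(one_zero, 0.0, p)
    return stat, p


def _paired_t_rows(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise paired t statistic and two-sided p on difference rows."""
    n = d.shape[1]
    m = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    zero_sd = sd == 0
    p = np.where(zero_sd & (m == 0), 1.0, p)
    p = np.where(zero_sd & (m != 0), _TINY_P, p)
    t = np.where(zero_sd & (m == 0), 0.0, t)
    return t, np.minimum(p, 1.0)


def site_tests_matrix(
    a: np.ndarray, b: np.ndarray, bartlett_alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Routed two-sided site tests for every row of pair-aligned matrices.

    Returns (p-values, parametric mask). The parametric branch is fully
    vectorised; rank-sum rows fall back to the per-row exact/asymptotic test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _, bart_p = _bartlett_rows(a, b)
    parametric = bart_p > bartlett_alpha
    pvals = np.ones(a.shape[0])
    if parametric.any():
        _, pvals[parametric] = _paired_t_rows(a[parametric] - b[parametric])
    for i in np.nonzero(~parametric)[0]:
        _, pvals[i] = rank_sum_pvalue(a[i], b[i])
    return pvals, parametric


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
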