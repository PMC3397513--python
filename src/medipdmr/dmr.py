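"""Seed-and-extend caller for differentially methylated regions (DMRs).

The method works on read depth at CpG sites in a paired two-group design
(each animal contributes one sample per group). Per CpG, a Bartlett-routed
two-sided test (paired t or Wilcoxon rank-sum; see :mod:`medipdmr.stats`)
selects highly variable sites (p < seed alpha) as seeds. Each seed is
extended along increasing genomic coordinate, incorporating adjacent CpGs
one at a time as long as (i) the gap to the next CpG is at most ``max_gap``
bp and (ii) the routed test on the region's per-sample average depth stays
below the region alpha. Candidates from nearby seeds that share member CpGs
are unioned and retested. Region significance is then assessed by a
permutation test (within-pair label swaps for the paired branch, full group
relabelings for the rank-sum branch), p-values are Benjamini-Hochberg
corrected, and a region is reported as a DMR when its q-value passes the FDR
level and at least ``min_sig_cpgs`` member CpGs are individually significant
at the seed alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .core import CpGMap, DepthMatrix
from .stats import (
    NONPARAMETRIC,
    PARAMETRIC,
    TestChoice,
    bh_adjust,
    paired_t_pvalue,
    rank_sum_pvalue,
    route_test,
    site_test,
    site_tests_matrix,
)

__all__ = [
    "DMRParams",
    "CandidateRegion",
    "DMR",
    "find_seed_cpgs",
    "extend_seed",
    "merge_candidates",
    "region_significance",
    "call_dmrs",
    "cpg_chain_coverage",
    "dmrs_to_frame",
]


@dataclass(frozen=True)
class DMRParams:
    """Tuning parameters of the DMR caller (defaults follow the method)."""

    seed_alpha: float = 0.01
    region_alpha: float = 0.01
    bartlett_alpha: float = 0.05
    max_gap: int = 200
    min_sig_cpgs: int = 5
    fdr: float = 0.01
    n_permutations: int = 1000
    min_distinct_permutations: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seed_alpha", "region_alpha", "bartlett_alpha", "fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.min_sig_cpgs < 1:
            raise ValueError("min_sig_cpgs must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class CandidateRegion:
    """A contiguous run of CpGs under consideration as a DMR."""

    chrom: str
    start: int
    end: int
    rows: tuple[int, ...]  # global CpG row indices, genomic order
    p_value: float
    test: TestChoice

    @property
    def n_cpgs(self) -> int:
        return len(self.rows)


@dataclass
class DMR(CandidateRegion):
    """A called differentially methylated region."""

    q_value: float = np.nan
    direction: str = ""
    n_sig_cpgs: int = 0
    mean_depth_a: float = np.nan
    mean_depth_b: float = np.nan
    permutation_fallback: bool = False


def _region_bounds(cpg_map: CpGMap, chrom: str, rows: tuple[int, ...]) -> tuple[int, int]:
    sl = cpg_map.row_slices()[chrom]
    pos = cpg_map.positions[chrom]
    first = pos[rows[0] - sl.start]
    last = pos[rows[-1] - sl.start]
    return int(first), int(last) + 2  # span the CpG dinucleotide


def _region_means(matrix: DepthMatrix, rows) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample average depth over the member CpGs, pair-aligned (A, B)."""
    a, b = matrix.group_depths(np.asarray(rows, dtype=np.intp))
    return a.mean(axis=0), b.mean(axis=0)


def _routed_region_test(
    matrix: DepthMatrix, rows, params: DMRParams
) -> tuple[float, TestChoice, np.ndarray, np.ndarray]:
    ma, mb = _region_means(matrix, rows)
    choice = route_test(ma, mb, params.bartlett_alpha)
    p = site_test(ma, mb, choice)
    return p, choice, ma, mb


def find_seed_cpgs(
    matrix: DepthMatrix, params: DMRParams
) -> tuple[np.ndarray, np.ndarray]:
    """Seed CpGs (routed site test p < seed alpha) in genomic order.

    Returns (seed row indices, p-values for *all* CpGs); the full p vector
    is reused later for the min-significant-CpG rule.
    """
    a, b = matrix.group_depths()
    pvals, _ = site_tests_matrix(a, b, params.bartlett_alpha)
    seeds = np.nonzero(pvals < params.seed_alpha)[0]
    return seeds, pvals


def extend_seed(
    seed_row: int,
    matrix: DepthMatrix,
    params: DMRParams,
    site_pvals: np.ndarray | None = None,
) -> CandidateRegion:
    """Grow a candidate region rightward from a significant seed CpG.

    The next CpG (increasing coordinate) is incorporated unless it lies more
    than ``max_gap`` bp past the current last member, the chromosome ends,
    or its inclusion lifts the routed region test to p >= region alpha — in
    which case it is excluded and extension stops. The recorded p is the
    region test on the final member set.
    """
    if site_pvals is not None and not site_pvals[seed_row] < params.seed_alpha:
        raise ValueError("extend_seed called on a non-significant CpG")
    cpg_map = matrix.cpg_map
    chrom = next(c for c, sl in cpg_map.row_slices().items() if sl.start <= seed_row < sl.stop)
    sl = cpg_map.row_slices()[chrom]
    pos = cpg_map.positions[chrom]

    rows = [seed_row]
    p, choice, _, _ = _routed_region_test(matrix, rows, params)
    nxt = seed_row + 1
    while nxt < sl.stop:
        gap = pos[nxt - sl.start] - pos[rows[-1] - sl.start]
        if gap > params.max_gap:
            break
        p_new, choice_new, _, _ = _routed_region_test(matrix, rows + [nxt], params)
        if p_new >= params.region_alpha:
            break
        rows.append(nxt)
        p, choice = p_new, choice_new
        nxt += 1
    start, end = _region_bounds(cpg_map, chrom, tuple(rows))
    return CandidateRegion(chrom, start, end, tuple(rows), p, choice)


def merge_candidates(
    regions: list[CandidateRegion], matrix: DepthMatrix, params: DMRParams
) -> list[CandidateRegion]:
    """Union candidates that share member CpGs; retest each union."""
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: (r.chrom, r.rows[0]))
    merged: list[CandidateRegion] = []
    cur_rows = set(regions[0].rows)
    cur_chrom = regions[0].chrom
    out_groups: list[tuple[str, set[int]]] = []
    for r in regions[1:]:
        if r.chrom == cur_chrom and cur_rows & set(r.rows):
            cur_rows |= set(r.rows)
        else:
            out_groups.append((cur_chrom, cur_rows))
            cur_chrom, cur_rows = r.chrom, set(r.rows)
    out_groups.append((cur_chrom, cur_rows))
    for chrom, rows in out_groups:
        rows_t = tuple(sorted(rows))
        p, choice, _, _ = _routed_region_test(matrix, rows_t, params)
        start, end = _region_bounds(matrix.cpg_map, chrom, rows_t)
        merged.append(CandidateRegion(chrom, start, end, rows_t, p, choice))
    return merged


def _paired_perm_p(
    diffs: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation p by within-pair label swaps (sign flips of differences)."""
    n = diffs.size
    sd = diffs.std(ddof=1)
    m = diffs.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.inf if sd == 0 and m != 0 else (0.0 if sd == 0 else m / (sd / np.sqrt(n)))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flipped = diffs[None, :] * signs
    ms = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(sds == 0, np.where(ms == 0, 0.0, np.inf), ms / (sds / np.sqrt(n)))
    hits = int(np.sum(np.abs(ts) >= abs(obs) - 1e-12))
    return (1 + hits) / (1 + n_perm)


def _ranksum_perm_p(
    values: np.ndarray, n1: int, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation p over full group relabelings; statistic = centered rank sum."""
    from scipy.stats import rankdata

    ranks = rankdata(values)
    mu = n1 * (values.size + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    idx = np.argsort(rng.random((n_perm, values.size)), axis=1)[:, :n1]
    perm = np.abs(ranks[idx].sum(axis=1) - mu)
    hits = int(np.sum(perm >= obs - 1e-12))
    return (1 + hits) / (1 + n_perm)


def region_significance(
    regions: list[CandidateRegion],
    matrix: DepthMatrix,
    params: DMRParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-value per candidate region.

    Within-pair label swaps for the paired-t branch (2^n_pairs distinct
    relabelings) and full group-label permutations for the rank-sum branch
    (C(2n, n) distinct). The +1/+1 Monte-Carlo estimator avoids zero
    p-values. When fewer distinct permutations exist than
    ``min_distinct_permutations`` the analytic routed-test p is reported
    instead and flagged.

    Returns (p-values, analytic-fallback flags).
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    n_pairs = matrix.design.n_pairs
    pvals = np.empty(len(regions))
    fallback = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        ma, mb = _region_means(matrix, r.rows)
        if r.test.choice == PARAMETRIC:
            distinct = 2**n_pairs
            if distinct < params.min_distinct_permutations:
                pvals[i] = r.p_value
                fallback[i] = True
            else:
                pvals[i] = _paired_perm_p(ma - mb, params.n_permutations, rng)
        else:
            distinct = comb(2 * n_pairs, n_pairs)
            if distinct < params.min_distinct_permutations:
                pvals[i] = r.p_value
                fallback[i] = True
            else:
                pvals[i] = _ranksum_perm_p(
                    np.concatenate([ma, mb]), n_pairs, params.n_permutations, rng
                )
    return pvals, fallback


def call_dmrs(matrix: DepthMatrix, params: DMRParams | None = None) -> list[DMR]:
    """Run the full seed → extend → merge → permute → BH pipeline."""
    if params is None:
        params = DMRParams()
    seeds, site_pvals = find_seed_cpgs(matrix, params)
    candidates = [extend_seed(int(s), matrix, params, site_pvals) for s in seeds]
    candidates = merge_candidates(candidates, matrix, params)
    if not candidates:
        return []
    rng = np.random.default_rng(params.rng_seed)
    perm_p, fallback = region_significance(candidates, matrix, params, rng)
    qvals = bh_adjust(perm_p)
    la, lb = matrix.design.group_labels
    out: list[DMR] = []
    for r, pp, q, fb in zip(candidates, perm_p, qvals, fallback):
        if q >= params.fdr:
            continue
        n_sig = int(np.sum(site_pvals[list(r.rows)] < params.seed_alpha))
        if n_sig < params.min_sig_cpgs:
            continue
        ma, mb = _region_means(matrix, r.rows)
        direction = la if ma.mean() > mb.mean() else lb
        out.append(
            DMR(
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                rows=r.rows,
                p_value=pp,
                test=r.test,
                q_value=float(q),
                direction=direction,
                n_sig_cpgs=n_sig,
                mean_depth_a=float(ma.mean()),
                mean_depth_b=float(mb.mean()),
                permutation_fallback=bool(fb),
            )
        )
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def cpg_chain_coverage(cpg_map: CpGMap, max_gap: int = 200) -> float:
    """Fraction of CpGs whose nearest neighbouring CpG is within ``max_gap`` bp.

    This is the fraction of sites reachable by the extension rule, i.e. the
    proportion of the genome's CpGs that chains of <= ``max_gap`` spacing
    cover.
    """
    covered = 0
    total = 0
    for pos in cpg_map.positions.values():
        total += pos.size
        if pos.size < 2:
            continue
        gaps = np.diff(pos)
        near_prev = np.concatenate([[np.iinfo(np.int64).max], gaps])
        near_next = np.concatenate([gaps, [np.iinfo(np.int64).max]])
        covered += int(np.sum(np.minimum(near_prev, near_next) <= max_gap))
    return covered / total


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Tabular view of called DMRs (one row per region)."""
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "n_cpgs": d.n_cpgs,
                "n_sig_cpgs": d.n_sig_cpgs,
                "region_p": d.p_value,
                "q": d.q_value,
                "direction": d.direction,
                "mean_depth_a": d.mean_depth_a,
                "mean_depth_b": d.mean_depth_b,
                "test_branch": d.test.choice,
                "analytic_fallback": d.permutation_fallback,
            }
            for d in dmrs
        ],
        columns=[
            "chrom", "start", "end", "n_cpgs", "n_sig_cpgs", "region_p", "q",
            "direction", "mean_depth_a", "mean_depth_b", "test_branch",
            "analytic_fallback",
        ],
    )
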