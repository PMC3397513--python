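"""Probe filtering and promoter methylation–expression correlation.

Microarray probes are admitted only when they map to a single genomic
location overlapping an exon of exactly one gene, and genes represented by
more than one surviving probe are discarded — leaving a one-probe-one-gene
expression table. For each such gene with a DMR in a promoter sub-region,
the methylation change is summarised as the log2 ratio of group mean depths
over the DMR CpGs in that sub-region, and correlated (Pearson) against the
log2 expression ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import FeatureSet
from .core import DepthMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeHit",
    "ProbeAlignment",
    "FilterReport",
    "filter_unique_probes",
    "promoter_methylation_ratio",
    "correlate_meth_expr",
    "PROMOTER_SUBREGIONS",
]

PROMOTER_SUBREGIONS = ("whole", "distal", "intermediate", "proximal")

_SUBREGION_CLASSES = {
    "distal": ("distal_promoter",),
    "intermediate": ("intermediate_promoter",),
    "proximal": ("proximal_promoter",),
    "whole": ("distal_promoter", "intermediate_promoter", "proximal_promoter"),
}


@dataclass(frozen=True)
class ProbeHit:
    chrom: str
    start: int
    end: int
    gene_id: str | None  # gene whose locus the hit falls in, if any
    exon_overlap: bool


@dataclass(frozen=True)
class ProbeAlignment:
    """All genomic hits of one probe (60-mer array probe semantics)."""

    probe_id: str
    hits: tuple[ProbeHit, ...]


@dataclass(frozen=True)
class FilterReport:
    """Stage counts of the probe uniqueness filter, with percentages of the
    initial probe count (two decimals, matching how such yields are quoted)."""

    n_initial: int
    n_unique_exon: int
    n_final: int

    @property
    def pct_unique_exon(self) -> float:
        return round(100.0 * self.n_unique_exon / self.n_initial, 2)

    @property
    def pct_final(self) -> float:
        return round(100.0 * self.n_final / self.n_initial, 2)


def filter_unique_probes(
    alignments: list[ProbeAlignment],
) -> tuple[dict[str, str], FilterReport]:
    """Two-stage probe filter → (gene_id → probe_id map, stage report).

    Stage 1 keeps probes with exactly one genomic hit, and that hit overlaps
    an exon of exactly one gene. Stage 2 drops every gene matched by more
    than one surviving probe, so each kept probe uniquely represents one
    gene.
    """
    stage1: list[tuple[str, str]] = []  # (probe, gene)
    for a in alignments:
        if len(a.hits) != 1:
            continue
        h = a.hits[0]
        if h.exon_overlap and h.gene_id is not None:
            stage1.append((a.probe_id, h.gene_id))
    per_gene: dict[str, list[str]] = {}
    for probe, gene in stage1:
        per_gene.setdefault(gene, []).append(probe)
    gene_probe = {g: ps[0] for g, ps in per_gene.items() if len(ps) == 1}
    report = FilterReport(len(alignments), len(stage1), len(gene_probe))
    return gene_probe, report


def promoter_methylation_ratio(
    matrix: DepthMatrix,
    dmrs,
    features: FeatureSet,
    gene_id: str,
    sub_region: str = "whole",
    dmr_restricted: bool = True,
) -> float | None:
    """log2 group-A/group-B depth ratio over a gene's promoter sub-region.

    By default only CpGs lying inside DMRs that overlap the sub-region
    contribute (the change being correlated is the one the DMR caller
    found); with ``dmr_restricted=False`` every sub-region CpG counts, but
    the gene still must carry at least one promoter DMR to be eligible.
    A pseudocount of 0.5 on each group mean guards zero depths. Returns
    ``None`` when no qualifying CpG exists (gene excluded).
    """
    if sub_region not in _SUBREGION_CLASSES:
        raise ValueError(f"unknown sub-region {sub_region!r}")
    sub_ivs = [
        (c, s, e)
        for cls in _SUBREGION_CLASSES[sub_region]
        for (c, s, e, _, g) in features.intervals[cls]
        if g == gene_id
    ]
    if not sub_ivs:
        logger.info("%s: no promoter intervals", gene_id)
        return None
    dmr_ivs = [
        (d.chrom, d.start, d.end)
        for d in dmrs
        if any(d.chrom == c and d.start < e and s < d.end for (c, s, e) in sub_ivs)
    ]
    if not dmr_ivs:
        logger.info("%s: no DMR overlapping the %s promoter", gene_id, sub_region)
        return None

    rows: list[int] = []
    for chrom, sl in matrix.cpg_map.row_slices().items():
        pos = matrix.cpg_map.positions[chrom]
        in_sub = np.zeros(pos.size, dtype=bool)
        for (c, s, e) in sub_ivs:
            if c == chrom:
                in_sub |= (pos >= s) & (pos < e)
        if dmr_restricted:
            in_dmr = np.zeros(pos.size, dtype=bool)
            for (c, s, e) in dmr_ivs:
                if c == chrom:
                    in_dmr |= (pos >= s) & (pos < e)
            in_sub &= in_dmr
        rows.extend((np.nonzero(in_sub)[0] + sl.start).tolist())
    if not rows:
        logger.info("%s: no qualifying CpGs in the %s promoter", gene_id, sub_region)
        return None
    a, b = matrix.group_depths(np.asarray(rows, dtype=np.intp))
    return float(np.log2((a.mean() + 0.5) / (b.mean() + 0.5)))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n_genes: int
    slope: float
    intercept: float


def correlate_meth_expr(
    meth: pd.DataFrame, expr: pd.DataFrame
) -> CorrelationResult:
    """Pearson correlation of promoter methylation vs expression ratios.

    Both frames carry ``gene_id`` plus a value column (``log2_meth_ratio``
    and ``log2_expr_ratio``); genes present in both are matched. Returns r,
    the two-sided p from the t transform on n−2 df, and the least-squares
    line (expression on methylation) for plotting.
    """
    merged = meth.merge(expr, on="gene_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 genes with both measurements")
    x = merged["log2_meth_ratio"].to_numpy(dtype=float)
    y = merged["log2_expr_ratio"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(float(r), float(p), len(merged), float(slope), float(intercept))
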