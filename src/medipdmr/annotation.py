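"""Ten-feature gene-structure annotation and DMR-to-feature assignment.

A gene's 2,700-bp promoter is split relative to its TSS into proximal
(−200..+500), intermediate (−1000..−200) and distal (−2200..−1000)
sub-regions, mirrored on the minus strand. Together with first/internal/
last exons, first/internal introns, the 2-kb region downstream of the TES
and the intergenic complement, these form the ten feature classes DMRs are
assigned to. All intervals are 0-based half-open and clipped to chromosome
bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CpGMap

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "GeneModels",
    "FeatureSet",
    "FEATURE_CLASSES",
    "build_features",
    "assign_dmrs_to_features",
    "cpg_pct_in_dmrs",
]

FEATURE_CLASSES = (
    "distal_promoter",
    "intermediate_promoter",
    "proximal_promoter",
    "first_exon",
    "first_intron",
    "internal_exons",
    "internal_introns",
    "last_exon",
    "downstream_2kb",
    "intergenic",
)

# promoter sub-region offsets relative to the TSS, transcription orientation:
# proximal −200..+500, intermediate −1000..−200, distal −2200..−1000
_PROMOTER_OFFSETS = {
    "proximal_promoter": (-200, 500),
    "intermediate_promoter": (-1000, -200),
    "distal_promoter": (-2200, -1000),
}
PROMOTER_SPAN = 2700  # total promoter width in bp
DOWNSTREAM_BP = 2000


@dataclass(frozen=True)
class Gene:
    """One gene model: exons as genomic-sorted 0-based half-open intervals."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("gene needs at least one exon")
        for (s, e) in exons:
            if e <= s:
                raise ValueError("empty exon interval")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError("exons overlap or are unsorted")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start as a boundary coordinate."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons in 5'→3' transcription order."""
        return list(self.exons) if self.strand == "+" else list(self.exons[::-1])

    def introns_tx_order(self) -> list[tuple[int, int]]:
        gaps = [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]
        return gaps if self.strand == "+" else gaps[::-1]


@dataclass
class GeneModels:
    genes: list[Gene]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class FeatureSet:
    """Per-class strand-resolved intervals: (chrom, start, end, strand, gene_id)."""

    intervals: dict[str, list[tuple[str, int, int, str, str]]]
    chrom_lengths: dict[str, int]

    def frame(self) -> pd.DataFrame:
        rows = [
            {"feature": cls, "chrom": c, "start": s, "end": e, "strand": st, "gene_id": g}
            for cls, ivs in self.intervals.items()
            for (c, s, e, st, g) in ivs
        ]
        return pd.DataFrame(
            rows, columns=["feature", "chrom", "start", "end", "strand", "gene_id"]
        )


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _complement(ivs: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out, cur = [], 0
    for s, e in _merge_intervals(ivs):
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        out.append((cur, length))
    return out


def _clip(s: int, e: int, length: int) -> tuple[int, int] | None:
    cs, ce = max(s, 0), min(e, length)
    if cs != s or ce != e:
        logger.warning("interval [%d, %d) clipped to chromosome bounds", s, e)
    return (cs, ce) if ce > cs else None


def _oriented(tss: int, strand: str, lo: int, hi: int) -> tuple[int, int]:
    """Map transcription-frame offsets (lo, hi) around the TSS to genome frame."""
    if strand == "+":
        return tss + lo, tss + hi
    return tss - hi, tss - lo


def build_features(genes: GeneModels, chrom_lengths: dict[str, int]) -> FeatureSet:
    """Compute the ten feature classes for a set of gene models."""
    ivs: dict[str, list[tuple[str, int, int, str, str]]] = {
        cls: [] for cls in FEATURE_CLASSES
    }

    def add(cls: str, gene: Gene, s: int, e: int) -> None:
        clipped = _clip(s, e, chrom_lengths[gene.chrom])
        if clipped:
            ivs[cls].append((gene.chrom, clipped[0], clipped[1], gene.strand, gene.gene_id))

    for g in genes:
        for cls, (lo, hi) in _PROMOTER_OFFSETS.items():
            add(cls, g, *_oriented(g.tss, g.strand, lo, hi))
        exons = g.exons_tx_order()
        add("first_exon", g, *exons[0])
        if len(exons) > 1:
            add("last_exon", g, *exons[-1])
        for ex in exons[1:-1]:
            add("internal_exons", g, *ex)
        introns = g.introns_tx_order()
        if introns:
            add("first_intron", g, *introns[0])
        for iv in introns[1:]:
            add("internal_introns", g, *iv)
        if g.strand == "+":
            add("downstream_2kb", g, g.tes, g.tes + DOWNSTREAM_BP)
        else:
            add("downstream_2kb", g, g.tes - DOWNSTREAM_BP, g.tes)

    # intergenic: per-chromosome complement of every gene-linked interval
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for cls in FEATURE_CLASSES[:-1]:
        for (c, s, e, _, _) in ivs[cls]:
            by_chrom[c].append((s, e))
    for chrom, length in chrom_lengths.items():
        for s, e in _complement(by_chrom[chrom], length):
            ivs["intergenic"].append((chrom, s, e, ".", ""))
    return FeatureSet(ivs, dict(chrom_lengths))


def _overlaps_any(
    chrom: str, start: int, end: int, ivs: list[tuple[str, int, int, str, str]]
) -> bool:
    return any(c == chrom and start < e and s < end for (c, s, e, _, _) in ivs)


def assign_dmrs_to_features(dmrs, features: FeatureSet) -> tuple[dict[str, int], list[list[str]]]:
    """Count DMRs per feature class (>= 1 bp overlap; classes not exclusive).

    ``dmrs`` is any iterable of objects with chrom/start/end attributes.
    Returns (per-class counts, per-DMR list of overlapped class labels).
    """
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    labels: list[list[str]] = []
    for d in dmrs:
        hit = [
            cls
            for cls in FEATURE_CLASSES
            if _overlaps_any(d.chrom, d.start, d.end, features.intervals[cls])
        ]
        for cls in hit:
            counts[cls] += 1
        labels.append(hit)
    return counts, labels


def cpg_pct_in_dmrs(dmrs, features: FeatureSet, cpg_map: CpGMap) -> dict[str, float]:
    """Percentage of each class's CpGs lying inside any DMR.

    A CpG belongs to an interval when its C position does. Classes with no
    CpGs report NaN (undefined).
    """
    dmr_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in dmrs:
        dmr_by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    in_dmr: dict[str, np.ndarray] = {}
    for chrom, pos in cpg_map.positions.items():
        mask = np.zeros(pos.size, dtype=bool)
        for s, e in dmr_by_chrom.get(chrom, []):
            mask |= (pos >= s) & (pos < e)
        in_dmr[chrom] = mask

    out: dict[str, float] = {}
    for cls in FEATURE_CLASSES:
        total = 0
        hit = 0
        for chrom, pos in cpg_map.positions.items():
            member = np.zeros(pos.size, dtype=bool)
            for (c, s, e, _, _) in features.intervals[cls]:
                if c == chrom:
                    member |= (pos >= s) & (pos < e)
            total += int(member.sum())
            hit += int((member & in_dmr[chrom]).sum())
        out[cls] = float("nan") if total == 0 else 100.0 * hit / total
    return out
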