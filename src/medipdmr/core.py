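"""Shared containers for the paired MeDIP-seq coverage analysis.

Coordinates are 0-based half-open throughout. A CpG site is identified by
the position of its cytosine; when emitted as an interval it spans the
dinucleotide, ``[pos, pos + 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CpGMap",
    "StudyDesign",
    "DepthMatrix",
    "TruthWindow",
    "TruthSet",
]


@dataclass(frozen=True)
class CpGMap:
    """Ordered CpG coordinates per chromosome.

    Parameters
    ----------
    positions
        Mapping of chromosome name to a strictly increasing integer array
        of C positions.
    chrom_lengths
        Chromosome lengths in bp.
    """

    positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            object.__setattr__(
                self, "positions", {**self.positions, chrom: pos}
            )
            if pos.size == 0:
                raise ValueError(f"{chrom}: chromosome has no CpGs")
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"{chrom}: CpG positions not strictly increasing")
            if chrom not in self.chrom_lengths:
                raise ValueError(f"{chrom}: missing chromosome length")
            if pos[-1] >= self.chrom_lengths[chrom]:
                raise ValueError(f"{chrom}: CpG position beyond chromosome end")

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n_cpgs(self) -> int:
        return sum(p.size for p in self.positions.values())

    def flat(self) -> pd.DataFrame:
        """All sites as a (chrom, pos) frame in global row order."""
        frames = [
            pd.DataFrame({"chrom": chrom, "pos": pos})
            for chrom, pos in self.positions.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def row_slices(self) -> dict[str, slice]:
        """Global row-index slice of each chromosome in matrix order."""
        out, start = {}, 0
        for chrom, pos in self.positions.items():
            out[chrom] = slice(start, start + pos.size)
            start += pos.size
        return out


@dataclass(frozen=True)
class StudyDesign:
    """Paired two-group design: each pair contributes one sample per group."""

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]  # one of the two group labels per sample
    pair_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.groups) != n or len(self.pair_ids) != n:
            raise ValueError("design columns have unequal lengths")
        labels = self.group_labels
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 groups, got {labels}")
        for pid in set(self.pair_ids):
            members = [g for g, p in zip(self.groups, self.pair_ids) if p == pid]
            if sorted(members) != sorted(labels):
                raise ValueError(f"pair {pid} lacks one sample per group")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def group_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)  # type: ignore[return-value]

    @property
    def n_pairs(self) -> int:
        return len(set(self.pair_ids))

    def group_columns(self, label: str) -> np.ndarray:
        """Column indices of one group, ordered by pair id.

        Both groups come back in the same pair order, so equal row index
        means same pair — the alignment the paired tests rely on.
        """
        pairs = sorted(set(self.pair_ids))
        idx = []
        for pid in pairs:
            for j, (g, p) in enumerate(zip(self.groups, self.pair_ids)):
                if p == pid and g == label:
                    idx.append(j)
        return np.asarray(idx, dtype=np.intp)

    def swap_groups(self) -> "StudyDesign":
        a, b = self.group_labels
        flipped = tuple(b if g == a else a for g in self.groups)
        return StudyDesign(self.sample_ids, flipped, self.pair_ids)

    @classmethod
    def paired(cls, n_pairs: int, labels: tuple[str, str] = ("sBF", "dBF")) -> "StudyDesign":
        """Convenience constructor: n_pairs animals, one sample per group each."""
        sids, grps, pids = [], [], []
        for i in range(n_pairs):
            for lab in labels:
                sids.append(f"{lab}_{i + 1}")
                grps.append(lab)
                pids.append(f"P{i + 1}")
        return cls(tuple(sids), tuple(grps), tuple(pids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.groups, "pair_id": self.pair_ids}
        )


@dataclass
class DepthMatrix:
    """Per-CpG × per-sample read depth with its map and design."""

    cpg_map: CpGMap
    depths: np.ndarray  # shape (n_cpgs, n_samples)
    design: StudyDesign

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 2:
            raise ValueError("depths must be 2-D")
        if self.depths.shape[0] != self.cpg_map.n_cpgs:
            raise ValueError("row count does not match CpG count")
        if self.depths.shape[1] != len(self.design.sample_ids):
            raise ValueError("column count does not match sample count")
        if np.any(self.depths < 0):
            raise ValueError("negative depths")

    @property
    def n_cpgs(self) -> int:
        return self.depths.shape[0]

    def group_depths(self, rows: np.ndarray | slice | None = None):
        """(A, B) depth sub-matrices with pair-aligned columns."""
        la, lb = self.design.group_labels
        ca = self.design.group_columns(la)
        cb = self.design.group_columns(lb)
        d = self.depths if rows is None else self.depths[rows]
        return d[..., ca], d[..., cb]


@dataclass(frozen=True)
class TruthWindow:
    """A planted differentially methylated window (simulation ground truth)."""

    chrom: str
    start: int
    end: int
    direction: str  # group label with elevated depth
    effect_size: float
    cpg_rows: tuple[int, ...]  # global row indices of member CpGs


@dataclass
class TruthSet:
    windows: list[TruthWindow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(
            w.chrom == chrom and start < w.end and w.start < end for w in self.windows
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": w.chrom,
                    "start": w.start,
                    "end": w.end,
                    "direction": w.direction,
                    "effect_size": w.effect_size,
                    "n_cpgs": len(w.cpg_rows),
                }
                for w in self.windows
            ]
        )
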