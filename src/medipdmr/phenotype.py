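"""Adipocyte-volume arithmetic and paired phenotype comparisons.

The mean adipocyte volume of a sample is computed from its diameter
histogram as

    V = (pi / 6) * sum(f_i * D_i**3) / sum(f_i)

with ``D_i`` the mean diameter of a cell class (geometric mean of the
cell's maximum and minimum diameter) in μm and ``f_i`` the number of cells
in that class; raw per-cell diameters are the special case f_i = 1.
Group contrasts (volume, fatty-acid composition) use the two-sided paired
Student's t-test, summarised as mean ± sample SD per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import paired_t_pvalue

__all__ = ["adipocyte_volume", "paired_group_compare", "GroupComparison", "volume_table"]


def adipocyte_volume(diameters, counts=None) -> float:
    """Mean adipocyte volume in μm³ from a diameter histogram.

    ``diameters`` in μm; ``counts`` defaults to one cell per entry.
    """
    d = np.asarray(diameters, dtype=float)
    f = np.ones_like(d) if counts is None else np.asarray(counts, dtype=float)
    if d.shape != f.shape:
        raise ValueError("diameters and counts must align")
    if np.any(d <= 0) or np.any(f < 0):
        raise ValueError("diameters must be positive and counts non-negative")
    total = f.sum()
    if total == 0:
        raise ValueError("no cells: sum of counts is zero")
    return float(np.pi / 6.0 * np.sum(f * d**3) / total)


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    n_pairs: int


def paired_group_compare(values_a, values_b) -> GroupComparison:
    """Two-sided paired t contrast of pair-aligned group vectors.

    Group summaries are mean ± sample SD (n−1 denominator).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    t, p = paired_t_pvalue(a - b)
    return GroupComparison(
        float(a.mean()), float(a.std(ddof=1)),
        float(b.mean()), float(b.std(ddof=1)),
        t, p, a.size,
    )


def volume_table(diameters: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean adipocyte volume from a long per-cell diameter table.

    Expects columns sample_id, group, pair_id, diameter (μm).
    """
    rows = [
        {
            "sample_id": sid,
            "group": g["group"].iloc[0],
            "pair_id": g["pair_id"].iloc[0],
            "n_cells": len(g),
            "volume_um3": adipocyte_volume(g["diameter"].to_numpy()),
        }
        for sid, g in diameters.groupby("sample_id", sort=False)
    ]
    return pd.DataFrame(rows)
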