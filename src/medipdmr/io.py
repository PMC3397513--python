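"""Readers and writers for the pipeline's plain-text interchange formats.

bedGraph, BED6 and BED12 are emitted 0-based half-open; a CpG's bedGraph
line spans its dinucleotide (start, start + 2). Tabular inputs/outputs are
TSV; run manifests are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Gene, GeneModels
from .core import CpGMap, DepthMatrix, StudyDesign, TruthSet
from .dmr import DMR, dmrs_to_frame

__all__ = [
    "write_bedgraph",
    "read_bedgraph_set",
    "write_chrom_sizes",
    "read_chrom_sizes",
    "write_design",
    "read_design",
    "write_truth_bed",
    "write_dmr_bed",
    "write_dmr_table",
    "write_gene_models_bed12",
    "read_gene_models_bed12",
    "write_manifest",
]


def write_bedgraph(path, cpg_map: CpGMap, depths: np.ndarray) -> None:
    """One sample's per-CpG depth track."""
    with open(path, "w") as fh:
        i = 0
        for chrom, pos in cpg_map.positions.items():
            for p in pos:
                fh.write(f"{chrom}\t{p}\t{p + 2}\t{depths[i]}\n")
                i += 1


def read_bedgraph_set(paths: list, design: StudyDesign) -> DepthMatrix:
    """Assemble a depth matrix from per-sample bedGraph tracks.

    Tracks must share the same sites in the same order; ``paths`` follows
    the design's sample order. Chromosome lengths are taken as the last
    covered end plus 1 kb when no sizes file is given.
    """
    tables = [
        pd.read_csv(p, sep="\t", header=None, names=["chrom", "start", "end", "depth"])
        for p in paths
    ]
    first = tables[0]
    for t in tables[1:]:
        if not (t["chrom"].equals(first["chrom"]) and t["start"].equals(first["start"])):
            raise ValueError("bedGraph tracks cover different CpG sites")
    positions = {
        str(chrom): grp["start"].to_numpy(dtype=np.int64)
        for chrom, grp in first.groupby("chrom", sort=False)
    }
    lengths = {c: int(p[-1]) + 1000 for c, p in positions.items()}
    depths = np.column_stack([t["depth"].to_numpy() for t in tables])
    return DepthMatrix(CpGMap(positions, lengths), depths, design)


def write_chrom_sizes(path, chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            chrom, length = line.split()
            out[chrom] = int(length)
    return out


def write_design(path, design: StudyDesign) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return StudyDesign(
        tuple(df["sample_id"]), tuple(df["group"]), tuple(df["pair_id"])
    )


def write_truth_bed(path, truth: TruthSet) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(truth.windows):
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\ttruth_{i + 1}\t0\t.\t{w.direction}\n"
            )


def write_dmr_bed(path, dmrs: list[DMR]) -> None:
    """BED6 with the BH q encoded as round(−10·log10 q) in the score column."""
    with open(path, "w") as fh:
        for i, d in enumerate(dmrs):
            score = int(round(-10 * np.log10(max(d.q_value, 1e-300))))
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tDMR_{i + 1}\t{score}\t.\n")


def write_dmr_table(path, dmrs: list[DMR]) -> None:
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", index=False)


def write_gene_models_bed12(path, genes: GeneModels) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_gene_models_bed12(path) -> GeneModels:
    genes = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + o, start + o + sz) for o, sz in zip(offs, sizes)
            )
            genes.append(Gene(f[3], chrom, f[5], exons))
    return GeneModels(genes)


def write_manifest(path, **params) -> None:
    """JSON sidecar recording every parameter (dataclasses serialised)."""
    def enc(v):
        if is_dataclass(v) and not isinstance(v, type):
            return asdict(v)
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, Path):
            return str(v)
        raise TypeError(f"not JSON-serialisable: {type(v)}")

    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, default=enc, sort_keys=True)
        fh.write("\n")
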