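#!/usr/bin/env python
"""Generate the synthetic paired backfat methylation study.

Ten animal pairs, ~8,000 clustered CpGs on two chromosomes with
negative-binomial MeDIP-seq-like depth (mean 30), 60 planted 3-fold
differential windows, 60 non-overlapping gene models, expression ratios
negatively coupled to each gene's measured promoter methylation change, and
group-shifted adipocyte/fatty-acid phenotypes. All downstream steps read
from results/study/.
"""

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np

from medipdmr import io as mio
from medipdmr.annotation import build_features
from medipdmr.core import StudyDesign
from medipdmr.expression import promoter_methylation_ratio
from medipdmr.simulate import (
    EVAL_N10,
    simulate_cpg_map,
    simulate_depth_matrix,
    simulate_expression,
    simulate_gene_models,
    simulate_phenotypes,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sim = replace(EVAL_N10, n_cpgs=8000, n_planted_dmrs=60, seed=SEED)
    design = StudyDesign.paired(10)

    cpg_map = simulate_cpg_map(sim)
    matrix, truth = simulate_depth_matrix(cpg_map, design, sim)
    genes = simulate_gene_models(cpg_map, 60, seed=SEED)

    # expression coupled to the *measured* promoter methylation change:
    # genes whose promoter holds a planted window inherit its depth shift
    features = build_features(genes, cpg_map.chrom_lengths)
    deltas = np.array(
        [
            promoter_methylation_ratio(
                matrix, truth.windows, features, g.gene_id, "whole",
                dmr_restricted=False,
            )
            or 0.0
            for g in genes
        ]
    )
    expr = simulate_expression(genes, deltas, coupling_beta=1.0, noise_sd=0.3,
                               seed=SEED + 1)
    dia, fat = simulate_phenotypes(design, seed=SEED + 2)

    for j, sid in enumerate(design.sample_ids):
        mio.write_bedgraph(OUT / f"{sid}.bedgraph", cpg_map, matrix.depths[:, j])
    mio.write_design(OUT / "design.tsv", design)
    mio.write_chrom_sizes(OUT / "chrom.sizes", cpg_map.chrom_lengths)
    mio.write_truth_bed(OUT / "truth.bed", truth)
    mio.write_gene_models_bed12(OUT / "genes.bed12", genes)
    expr.to_csv(OUT / "expression.tsv", sep="\t", index=False)
    dia.to_csv(OUT / "adipocyte_diameters.tsv", sep="\t", index=False)
    fat.to_csv(OUT / "fatty_acids.tsv", sep="\t", index=False)
    mio.write_manifest(OUT / "manifest.json", seed=SEED, sim=sim)

    n_promo = int(np.sum(deltas != 0.0))
    print(f"simulated {cpg_map.n_cpgs} CpGs, {len(truth)} planted windows, "
          f"{len(genes)} genes ({n_promo} with a planted promoter window)")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
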