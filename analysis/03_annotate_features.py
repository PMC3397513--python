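#!/usr/bin/env python
"""Assign called DMRs to the ten gene-structure features.

Builds promoter sub-regions (proximal/intermediate/distal), exon/intron
classes, TES-downstream and intergenic intervals from the simulated gene
models, counts DMRs per class (a DMR overlapping several classes counts in
each), and computes the percentage of each class's CpGs lying inside DMRs.
"""

from pathlib import Path

import pandas as pd

from medipdmr import io as mio
from medipdmr.annotation import assign_dmrs_to_features, build_features, cpg_pct_in_dmrs

ROOT = Path(__file__).resolve().parents[1] / "results"
STUDY = ROOT / "study"


def main() -> None:
    design = mio.read_design(STUDY / "design.tsv")
    matrix = mio.read_bedgraph_set(
        [STUDY / f"{sid}.bedgraph" for sid in design.sample_ids], design
    )
    genes = mio.read_gene_models_bed12(STUDY / "genes.bed12")
    dmrs = pd.read_csv(ROOT / "dmrs.tsv", sep="\t")
    dmr_ivs = list(dmrs[["chrom", "start", "end"]].itertuples(index=False))

    features = build_features(genes, mio.read_chrom_sizes(STUDY / "chrom.sizes"))
    counts, labels = assign_dmrs_to_features(dmr_ivs, features)
    pct = cpg_pct_in_dmrs(dmr_ivs, features, matrix.cpg_map)

    out = pd.DataFrame(
        {
            "feature": list(counts),
            "n_dmrs": list(counts.values()),
            "pct_cpgs_in_dmrs": [round(pct[f], 2) for f in counts],
        }
    )
    out.to_csv(ROOT / "feature_summary.tsv", sep="\t", index=False)
    dmrs["features"] = [",".join(l) for l in labels]
    dmrs.to_csv(ROOT / "dmrs_annotated.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    print(f"\nfeature summary written to {ROOT / 'feature_summary.tsv'}")


if __name__ == "__main__":
    main()
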