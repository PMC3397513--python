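#!/usr/bin/env python
"""Probe filtering and promoter methylation-expression correlation.

First reproduces the expression-array probe filter on a synthetic
43,603-probe alignment table (unique exon mapping, then one probe per
gene), then correlates the log2 promoter methylation ratio of genes with
promoter DMRs against their log2 expression ratio, for the whole promoter
and each sub-region.
"""

from pathlib import Path

import pandas as pd

from medipdmr import io as mio
from medipdmr.annotation import build_features
from medipdmr.expression import (
    PROMOTER_SUBREGIONS,
    correlate_meth_expr,
    filter_unique_probes,
    promoter_methylation_ratio,
)
from medipdmr.simulate import simulate_probe_alignments

ROOT = Path(__file__).resolve().parents[1] / "results"
STUDY = ROOT / "study"


def main() -> None:
    alignments = simulate_probe_alignments(seed=0)
    _, report = filter_unique_probes(alignments)
    print(
        f"probe filter: {report.n_initial} probes -> {report.n_unique_exon} "
        f"unique exon hits ({report.pct_unique_exon}%) -> {report.n_final} "
        f"one-probe-one-gene survivors ({report.pct_final}%)"
    )

    design = mio.read_design(STUDY / "design.tsv")
    matrix = mio.read_bedgraph_set(
        [STUDY / f"{sid}.bedgraph" for sid in design.sample_ids], design
    )
    genes = mio.read_gene_models_bed12(STUDY / "genes.bed12")
    features = build_features(genes, mio.read_chrom_sizes(STUDY / "chrom.sizes"))
    dmrs = pd.read_csv(ROOT / "dmrs.tsv", sep="\t")
    dmr_ivs = list(dmrs[["chrom", "start", "end"]].itertuples(index=False))
    expr = pd.read_csv(STUDY / "expression.tsv", sep="\t")

    rows = []
    for sr in PROMOTER_SUBREGIONS:
        meth = pd.DataFrame(
            [
                {"gene_id": g.gene_id, "log2_meth_ratio": m}
                for g in genes
                if (m := promoter_methylation_ratio(matrix, dmr_ivs, features,
                                                    g.gene_id, sr)) is not None
            ]
        )
        if len(meth) < 3:
            print(f"{sr}: only {len(meth)} genes with promoter DMRs; skipped")
            continue
        res = correlate_meth_expr(meth, expr)
        rows.append(
            {"sub_region": sr, "r": round(res.r, 3), "p": res.p_value,
             "n": res.n_genes, "slope": round(res.slope, 3),
             "intercept": round(res.intercept, 3)}
        )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "meth_expr_correlation.tsv", sep="\t", index=False)
    print("\n" + table.to_string(index=False))
    print("\nnegative r: genes gaining promoter methylation lose expression")


if __name__ == "__main__":
    main()
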