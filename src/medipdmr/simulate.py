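"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a paired two-group MeDIP-seq comparison of the two
backfat layers: clustered CpG positions (runs of closely spaced sites
separated by larger gaps, so both <=200 bp chains and >200 bp breaks occur),
negative-binomial read depth with per-sample size factors and a per-pair
random effect, planted differentially methylated windows with a known
multiplicative depth shift, gene models exercising all ten gene-structure
features, expression ratios negatively coupled to promoter methylation, and
group-shifted adipocyte-diameter and fatty-acid phenotypes.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotation import Gene, GeneModels
from .core import CpGMap, DepthMatrix, StudyDesign, TruthSet, TruthWindow

__all__ = [
    "SimulationParams",
    "simulate_cpg_map",
    "simulate_depth_matrix",
    "simulate_gene_models",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_probe_alignments",
    "EVAL_N10",
    "STUDY_N3",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study.

    Cluster geometry draws are uniform integers over inclusive ranges, so a
    degenerate range like ``(50, 50)`` yields fixed spacing. Depth is
    negative binomial with mean ``depth_mu`` and dispersion (NB size)
    ``depth_dispersion``, scaled per sample by a log-normal size factor and
    per pair by a log-normal random effect.
    """

    n_chroms: int = 2
    n_cpgs: int = 5000
    cluster_size: tuple[int, int] = (1, 15)  # CpGs per cluster
    within_spacing: tuple[int, int] = (20, 150)  # bp between clustered CpGs
    between_gap: tuple[int, int] = (300, 2000)  # bp between clusters
    depth_mu: float = 30.0
    depth_dispersion: float = 5.0
    size_factor_sd: float = 0.02  # log-normal sigma per sample (libraries sequenced to near-equal depth)
    pair_effect_sd: float = 0.1  # log-normal sigma per pair
    n_planted_dmrs: int = 20
    effect_size: float = 3.0
    dmr_n_cpgs: tuple[int, int] = (6, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mu <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mu and depth_dispersion must be positive")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        for name in ("cluster_size", "within_spacing", "between_gap", "dmr_n_cpgs"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) range")


def preset(name: str, seed: int = 0) -> tuple[SimulationParams, StudyDesign]:
    """Named study configurations.

    ``eval-n10``: ten pairs — enough for the permutation branch and for a
    nonparametric test to reach small p-values; the scale used for method
    evaluation. ``study-n3``: three animals per group, the study's own
    scale, at which the permutation test falls back to analytic p-values.
    """
    if name == "eval-n10":
        return replace(EVAL_N10, seed=seed), StudyDesign.paired(10)
    if name == "study-n3":
        return replace(STUDY_N3, seed=seed), StudyDesign.paired(3)
    raise ValueError(f"unknown preset {name!r}")


#: method-evaluation conditions (pair count lives in the StudyDesign)
EVAL_N10 = SimulationParams()

#: the deposited study's scale uses the same depth model
STUDY_N3 = SimulationParams()


def _draw(rng: np.random.Generator, lohi: tuple[int, int], size=None):
    return rng.integers(lohi[0], lohi[1] + 1, size=size)


def simulate_cpg_map(params: SimulationParams) -> CpGMap:
    """Clustered CpG positions over ``n_chroms`` chromosomes."""
    rng = np.random.default_rng(params.seed)
    per_chrom = np.full(params.n_chroms, params.n_cpgs // params.n_chroms)
    per_chrom[: params.n_cpgs % params.n_chroms] += 1
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for c, n in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        pos: list[int] = []
        cur = int(_draw(rng, params.between_gap))
        while len(pos) < n:
            k = int(_draw(rng, params.cluster_size))
            k = min(k, n - len(pos))
            pos.append(cur)
            for _ in range(k - 1):
                cur += int(_draw(rng, params.within_spacing))
                pos.append(cur)
            cur += int(_draw(rng, params.between_gap))
        arr = np.asarray(pos, dtype=np.int64)
        positions[chrom] = arr
        lengths[chrom] = int(arr[-1] + _draw(rng, params.between_gap) + 5000)
    return CpGMap(positions, lengths)


def _cluster_runs(cpg_map: CpGMap, max_gap: int = 200) -> list[tuple[str, int, int]]:
    """Maximal runs of adjacent CpGs spaced <= max_gap, as global row ranges."""
    runs = []
    for chrom, sl in cpg_map.row_slices().items():
        pos = cpg_map.positions[chrom]
        start = 0
        for i in range(1, pos.size + 1):
            if i == pos.size or pos[i] - pos[i - 1] > max_gap:
                runs.append((chrom, sl.start + start, sl.start + i))
                start = i
    return runs


def simulate_depth_matrix(
    cpg_map: CpGMap, design: StudyDesign, params: SimulationParams
) -> tuple[DepthMatrix, TruthSet]:
    """Negative-binomial depths with planted differential windows.

    Planted windows sit only inside CpG runs whose adjacent spacing is at
    most 200 bp, so the extension rule can recover them; window directions
    alternate between the two groups. With ``effect_size == 1`` nothing is
    planted and the truth set is empty.
    """
    rng = np.random.default_rng(params.seed + 1)
    n_sites = cpg_map.n_cpgs
    n_samples = len(design.sample_ids)
    la, lb = design.group_labels

    # planted windows inside <=200 bp runs
    windows: list[TruthWindow] = []
    effect = np.ones((n_sites, n_samples))
    n_wanted = 0 if params.effect_size == 1.0 else params.n_planted_dmrs
    if n_wanted:
        runs = [r for r in _cluster_runs(cpg_map) if r[2] - r[1] >= params.dmr_n_cpgs[0]]
        rng.shuffle(runs)
        if len(runs) < n_wanted:
            raise ValueError(
                f"only {len(runs)} eligible CpG runs for {n_wanted} planted windows"
            )
        group_cols = {lab: design.group_columns(lab) for lab in (la, lb)}
        for w, (chrom, lo, hi) in enumerate(runs[:n_wanted]):
            width = min(int(_draw(rng, params.dmr_n_cpgs)), hi - lo)
            off = int(rng.integers(0, hi - lo - width + 1))
            rows = tuple(range(lo + off, lo + off + width))
            up = la if w % 2 == 0 else lb
            effect[rows[0] : rows[-1] + 1, group_cols[up]] = params.effect_size
            sl = cpg_map.row_slices()[chrom]
            pos = cpg_map.positions[chrom]
            start = int(pos[rows[0] - sl.start])
            end = int(pos[rows[-1] - sl.start]) + 2
            windows.append(
                TruthWindow(chrom, start, end, up, params.effect_size, rows)
            )
        windows.sort(key=lambda w: (w.chrom, w.start))

    size_factors = rng.lognormal(0.0, params.size_factor_sd, size=n_samples)
    pair_order = sorted(set(design.pair_ids))
    pair_fx = dict(
        zip(pair_order, rng.lognormal(0.0, params.pair_effect_sd, size=len(pair_order)))
    )
    sample_pair_fx = np.array([pair_fx[p] for p in design.pair_ids])

    mean = params.depth_mu * effect * size_factors[None, :] * sample_pair_fx[None, :]
    k = params.depth_dispersion
    depths = rng.negative_binomial(k, k / (k + mean))
    return DepthMatrix(cpg_map, depths.astype(np.int64), design), TruthSet(windows)


def simulate_gene_models(cpg_map: CpGMap, n_genes: int, seed: int = 0) -> GeneModels:
    """Non-overlapping gene models exercising all ten structural features.

    Genes appear on both strands; the set always contains at least one
    2-exon gene and one gene with four or more exons (so internal exons and
    internal introns are populated). Each gene keeps 2,700 bp upstream and
    2,000 bp downstream clearance inside its chromosome.
    """
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return GeneModels([])
    chroms = list(cpg_map.chrom_lengths)
    margin_up, margin_down = 2700, 2000
    genes: list[Gene] = []
    per_chrom = np.full(len(chroms), n_genes // len(chroms))
    per_chrom[: n_genes % len(chroms)] += 1
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        length = cpg_map.chrom_lengths[chrom]
        slot = (length - margin_up - margin_down) // n_here
        if slot < 2100:
            raise ValueError(f"{chrom} too small to host {n_here} genes")
        body_max = min(8000, slot - 100)
        for i in range(n_here):
            slot_start = margin_up + i * slot
            body_len = int(rng.integers(2000, body_max + 1))
            start = slot_start + int(rng.integers(0, slot - body_len + 1))
            end = start + body_len
            strand = "+" if rng.random() < 0.5 else "-"
            if gid == 0:
                n_exons, strand = 2, "+"
            elif gid == 1:
                n_exons, strand = 4, "-"
            else:
                n_exons = int(rng.integers(1, 7))
            # partition the body into alternating exon/intron blocks
            n_blocks = 2 * n_exons - 1
            cuts = np.sort(rng.choice(np.arange(1, body_len), size=n_blocks - 1, replace=False)) if n_blocks > 1 else np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [body_len]])
            exons = [
                (start + int(bounds[i]), start + int(bounds[i + 1]))
                for i in range(0, n_blocks, 2)
            ]
            genes.append(Gene(f"G{gid + 1:04d}", chrom, strand, exons))
            gid += 1
    return GeneModels(genes)


def simulate_expression(
    genes: GeneModels,
    promoter_meth_delta: np.ndarray,
    coupling_beta: float = 0.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene log2 expression ratios negatively coupled to methylation.

    ``log2_expr_ratio = -beta * promoter_meth_delta + N(0, noise_sd)``: a
    gene whose promoter gains methylation in group A loses expression there.
    """
    if coupling_beta < 0:
        raise ValueError("coupling_beta must be >= 0")
    delta = np.asarray(promoter_meth_delta, dtype=float)
    if delta.size != len(genes.genes):
        raise ValueError("promoter_meth_delta length does not match gene count")
    rng = np.random.default_rng(seed)
    ratio = -coupling_beta * delta + rng.normal(0.0, noise_sd, size=delta.size)
    return pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes.genes], "log2_expr_ratio": ratio}
    )


def simulate_probe_alignments(
    n_probes: int = 43_603,
    n_unique_exon: int = 4_983,
    n_final: int = 3_074,
    seed: int = 0,
):
    """Synthetic microarray probe-alignment table with known filter yields.

    Builds ``n_probes`` 60-mer probe alignments of which exactly
    ``n_unique_exon`` have a single exon-overlapping hit in one gene, and
    exactly ``n_final`` genes end up represented by a single surviving probe
    (the remaining unique-exon probes share genes in groups of two or
    three). The defaults reproduce the yields of the study's expression
    array. Returns a list of :class:`~medipdmr.expression.ProbeAlignment`.
    """
    from .expression import ProbeAlignment, ProbeHit

    if not 0 <= n_final <= n_unique_exon <= n_probes:
        raise ValueError("need n_final <= n_unique_exon <= n_probes")
    extra = n_unique_exon - n_final
    if extra == 1:
        raise ValueError("cannot split one leftover probe across >= 2-probe genes")
    rng = np.random.default_rng(seed)
    aligns: list[ProbeAlignment] = []
    pid = 0

    def hit(gene: str | None, exonic: bool) -> ProbeHit:
        start = int(rng.integers(0, 10**8))
        return ProbeHit(f"chr{rng.integers(1, 19)}", start, start + 60, gene, exonic)

    for g in range(n_final):
        aligns.append(ProbeAlignment(f"p{pid}", (hit(f"GU{g}", True),)))
        pid += 1
    # genes carrying two probes each (plus one three-probe gene if extra is odd)
    g = 0
    while extra > 0:
        k = 3 if extra % 2 == 1 else 2
        for _ in range(k):
            aligns.append(ProbeAlignment(f"p{pid}", (hit(f"GM{g}", True),)))
            pid += 1
        extra -= k
        g += 1
    for _ in range(n_probes - n_unique_exon):
        if rng.random() < 0.5:  # multi-mapper
            aligns.append(ProbeAlignment(f"p{pid}", (hit("GX", True), hit("GY", True))))
        else:  # single hit outside any exon
            aligns.append(ProbeAlignment(f"p{pid}", (hit(None, False),)))
        pid += 1
    rng.shuffle(aligns)
    return aligns


# defaults mirror the reported depot composition (percent of total fatty
# acids, mean and SD): superficial layer vs deep layer
_FATTY_DEFAULTS = {
    "A": {"SFA": (35.63, 2.09), "MUFA": (44.92, 0.80), "PUFA": (19.45, 1.31)},
    "B": {"SFA": (37.39, 2.19), "MUFA": (43.54, 1.27), "PUFA": (19.06, 0.97)},
}


def simulate_phenotypes(
    design: StudyDesign,
    diameter_mean: dict[str, float] | None = None,
    diameter_sd: float = 15.0,
    fatty_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    n_cells: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adipocyte diameters and fatty-acid compositions per sample.

    Diameters (μm) are gamma-distributed around each group's mean — 100
    cells per sample by default, matching the measurement protocol.
    Superficial-layer adipocytes run larger, so group A defaults to a bigger
    mean diameter. Fatty-acid rows are drawn around group means and
    renormalised to sum to 100.

    Returns (diameters frame: sample_id, group, pair_id, diameter;
    fatty-acid frame: sample_id, group, pair_id, SFA, MUFA, PUFA).
    """
    la, lb = design.group_labels
    if diameter_mean is None:
        diameter_mean = {la: 90.0, lb: 80.0}
    if min(diameter_mean.values()) <= 0 or diameter_sd <= 0 or n_cells < 1:
        raise ValueError("diameter parameters must be positive, n_cells >= 1")
    if fatty_params is None:
        fatty_params = {la: _FATTY_DEFAULTS["A"], lb: _FATTY_DEFAULTS["B"]}
    for lab, comp in fatty_params.items():
        tot = sum(m for m, _ in comp.values())
        if abs(tot - 100.0) > 0.5:
            raise ValueError(f"group {lab} composition means sum to {tot}, not 100")

    rng = np.random.default_rng(seed)
    dia_rows, fat_rows = [], []
    for sid, grp, pid in zip(design.sample_ids, design.groups, design.pair_ids):
        m = diameter_mean[grp]
        shape = (m / diameter_sd) ** 2
        scale = diameter_sd**2 / m
        d = rng.gamma(shape, scale, size=n_cells)
        dia_rows.extend(
            {"sample_id": sid, "group": grp, "pair_id": pid, "diameter": float(x)}
            for x in d
        )
        comp = {}
        for cls, (mean, sd) in fatty_params[grp].items():
            comp[cls] = max(rng.normal(mean, sd), 0.0)
        tot = sum(comp.values())
        fat_rows.append(
            {
                "sample_id": sid,
                "group": grp,
                "pair_id": pid,
                **{cls: 100.0 * v / tot for cls, v in comp.items()},
            }
        )
    return pd.DataFrame(dia_rows), pd.DataFrame(fat_rows)
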