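"""Distributional and structural checks on the synthetic-data generators."""

import numpy as np
import pytest
from scipy.stats import kstest, pearsonr

from medipdmr.core import StudyDesign
from medipdmr.simulate import (
    SimulationParams,
    preset,
    simulate_cpg_map,
    simulate_depth_matrix,
    simulate_expression,
    simulate_gene_models,
    simulate_phenotypes,
)


class TestCpGMap:
    def test_same_seed_identical_maps(self):
        p = SimulationParams(seed=5)
        m1, m2 = simulate_cpg_map(p), simulate_cpg_map(p)
        assert m1.chrom_lengths == m2.chrom_lengths
        for c in m1.positions:
            assert np.array_equal(m1.positions[c], m2.positions[c])

    def test_degenerate_geometry_gives_fixed_spacings(self):
        p = SimulationParams(
            n_chroms=1, n_cpgs=100, cluster_size=(10, 10),
            within_spacing=(50, 50), between_gap=(500, 500), seed=1,
        )
        pos = simulate_cpg_map(p).positions["chr1"]
        gaps = np.diff(pos)
        assert set(gaps) == {50, 500}
        # 10 clusters of 10: every 10th gap is the 500 bp break, rest are 50
        assert np.all(gaps[9::10] == 500)
        mask = np.ones(gaps.size, dtype=bool)
        mask[9::10] = False
        assert np.all(gaps[mask] == 50)

    def test_both_tight_and_broken_spacings_occur(self):
        m = simulate_cpg_map(SimulationParams(seed=0))
        gaps = np.concatenate([np.diff(p) for p in m.positions.values()])
        assert np.any(gaps <= 200) and np.any(gaps > 200)

    def test_spacing_distribution_recovered(self):
        """Empirical spacings match an independent re-sampling of the stated
        uniform mixtures (two-sample KS on each component)."""
        p = SimulationParams(n_chroms=1, n_cpgs=10_000, seed=9)
        pos = simulate_cpg_map(p).positions["chr1"]
        gaps = np.diff(pos)
        within = gaps[gaps <= p.within_spacing[1]]
        between = gaps[gaps >= p.between_gap[0]]
        assert within.size + between.size == gaps.size  # ranges don't overlap
        rng = np.random.default_rng(1234)
        ref_within = rng.integers(p.within_spacing[0], p.within_spacing[1] + 1, within.size)
        ref_between = rng.integers(p.between_gap[0], p.between_gap[1] + 1, between.size)
        assert kstest(within, ref_within).pvalue > 0.01
        assert kstest(between, ref_between).pvalue > 0.01

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(within_spacing=(0, 10))
        with pytest.raises(ValueError):
            SimulationParams(between_gap=(100, 50))


class TestDepthMatrix:
    def test_null_configuration_empty_truth_and_equal_means(self, design10):
        p = SimulationParams(n_chroms=1, n_cpgs=2000, effect_size=1.0, seed=2)
        matrix, truth = simulate_depth_matrix(simulate_cpg_map(p), design10, p)
        assert len(truth) == 0
        a, b = matrix.group_depths()
        # grand means agree within sampling error; the dominant term is the
        # per-sample size-factor draw (sigma 0.02, 10 samples per group)
        se_counts = matrix.depths.std() / np.sqrt(a.size)
        se_sf = matrix.depths.mean() * 0.02 * np.sqrt(2 / 10)
        assert abs(a.mean() - b.mean()) < 4 * np.hypot(se_counts, se_sf)

    def test_planted_effect_matches_generative_formula(self):
        """Mean depth in planted windows ~ 3x for the elevated group, checked
        against an independent re-simulation of the stated NB model."""
        design = StudyDesign.paired(10)
        p = SimulationParams(n_cpgs=5000, effect_size=3.0, depth_mu=30.0, seed=6)
        matrix, truth = simulate_depth_matrix(simulate_cpg_map(p), design, p)
        la, lb = design.group_labels
        ratios = []
        for w in truth.windows:
            rows = np.asarray(w.cpg_rows)
            a, b = matrix.group_depths(rows)
            up, dn = (a, b) if w.direction == la else (b, a)
            ratios.append(up.mean() / dn.mean())
        observed = np.mean(ratios)
        # independent oracle: simulate the stated formula directly
        rng = np.random.default_rng(99)
        k, mu = p.depth_dispersion, p.depth_mu
        hi = rng.negative_binomial(k, k / (k + 3 * mu), size=200_000).mean()
        lo = rng.negative_binomial(k, k / (k + mu), size=200_000).mean()
        assert observed == pytest.approx(hi / lo, rel=0.1)

    def test_same_seed_identical_matrices(self, design10):
        p = SimulationParams(n_chroms=1, n_cpgs=500, seed=3)
        m = simulate_cpg_map(p)
        d1, t1 = simulate_depth_matrix(m, design10, p)
        d2, t2 = simulate_depth_matrix(m, design10, p)
        assert np.array_equal(d1.depths, d2.depths)
        assert t1.to_frame().equals(t2.to_frame())

    def test_truth_windows_nonoverlapping_and_cpg_bearing(self, design10):
        p = SimulationParams(seed=8)
        m = simulate_cpg_map(p)
        _, truth = simulate_depth_matrix(m, design10, p)
        assert len(truth) == p.n_planted_dmrs
        frame = truth.to_frame().sort_values(["chrom", "start"])
        for c, grp in frame.groupby("chrom"):
            starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
            assert np.all(starts[1:] >= ends[:-1])
        for w in truth.windows:
            assert len(w.cpg_rows) >= 1

    def test_too_many_windows_rejected(self, design10):
        p = SimulationParams(n_chroms=1, n_cpgs=60, n_planted_dmrs=50, seed=1)
        with pytest.raises(ValueError):
            simulate_depth_matrix(simulate_cpg_map(p), design10, p)


class TestGeneModels:
    def test_zero_genes_gives_empty_set(self):
        m = simulate_cpg_map(SimulationParams(seed=0))
        assert len(simulate_gene_models(m, 0)) == 0

    def test_structural_validator_over_random_genes(self):
        """Every generated gene passes an independent structural check."""
        m = simulate_cpg_map(SimulationParams(seed=4))
        genes = simulate_gene_models(m, 30, seed=7)
        assert len(genes) == 30
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}
        n_exons = sorted(len(g.exons) for g in genes)
        assert 2 in n_exons and n_exons[-1] >= 4
        bodies = {}
        for g in genes:
            for (s, e) in g.exons:
                assert 0 <= s < e <= m.chrom_lengths[g.chrom]
            for (s0, e0), (s1, e1) in zip(g.exons, g.exons[1:]):
                assert e0 <= s1  # sorted, non-overlapping
            assert g.start >= 2700 and g.end + 2000 <= m.chrom_lengths[g.chrom]
            bodies.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in bodies.values():
            ivs.sort()
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                assert e0 <= s1  # gene bodies do not overlap

    def test_forced_four_exon_gene_structure(self):
        m = simulate_cpg_map(SimulationParams(seed=4))
        genes = simulate_gene_models(m, 5, seed=7)
        four = next(g for g in genes if len(g.exons) == 4)
        assert len(four.exons_tx_order()) == 4
        assert len(four.introns_tx_order()) == 3


class TestExpression:
    def _setup(self, n_genes=500, seed=0):
        m = simulate_cpg_map(SimulationParams(seed=seed))
        genes = simulate_gene_models(m, 40, seed=seed)
        return genes

    def test_zero_coupling_gives_no_correlation(self):
        genes = self._setup()
        rng = np.random.default_rng(0)
        delta = rng.normal(0, 1, len(genes.genes))
        expr = simulate_expression(genes, delta, coupling_beta=0.0, noise_sd=0.5, seed=1)
        r, _ = pearsonr(delta, expr["log2_expr_ratio"])
        assert abs(r) < 0.4  # 40 genes: null r fluctuates within ~2.5/sqrt(n)

    def test_noise_free_unit_coupling_is_exactly_minus_one(self):
        genes = self._setup()
        rng = np.random.default_rng(2)
        delta = rng.normal(0, 1, len(genes.genes))
        expr = simulate_expression(genes, delta, coupling_beta=1.0, noise_sd=0.0, seed=3)
        r, _ = pearsonr(delta, expr["log2_expr_ratio"])
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_attenuated_correlation_matches_closed_form(self):
        """Observed r ~ −β·SD(δ)/sqrt(β²·Var(δ)+σ²) at β=0.5, σ=0.5."""
        m = simulate_cpg_map(SimulationParams(n_chroms=1, n_cpgs=5000, seed=5))
        genes = simulate_gene_models(m, 60, seed=5)
        beta, noise = 0.5, 0.5
        rs = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            delta = rng.normal(0, 1.0, len(genes.genes))
            expr = simulate_expression(genes, delta, beta, noise, seed=200 + rep)
            r, _ = pearsonr(delta, expr["log2_expr_ratio"])
            sd = delta.std()
            expected = -beta * sd / np.sqrt(beta**2 * sd**2 + noise**2)
            rs.append(r - expected)
        assert abs(np.mean(rs)) < 0.08

    def test_mismatched_gene_set_rejected(self):
        genes = self._setup()
        with pytest.raises(ValueError):
            simulate_expression(genes, np.zeros(len(genes.genes) + 1))


class TestPhenotypes:
    def test_defaults_are_deterministic(self, design10):
        d1, f1 = simulate_phenotypes(design10, seed=4)
        d2, f2 = simulate_phenotypes(design10, seed=4)
        assert d1.equals(d2) and f1.equals(f2)

    def test_hundred_cells_per_sample_and_rows_sum_100(self, design10):
        dia, fat = simulate_phenotypes(design10, seed=1)
        assert dia.groupby("sample_id").size().eq(100).all()
        sums = fat[["SFA", "MUFA", "PUFA"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=0.5)

    def test_negative_parameters_rejected(self, design10):
        with pytest.raises(ValueError):
            simulate_phenotypes(design10, diameter_mean={"sBF": -5.0, "dBF": 80.0})

    def test_identical_groups_yield_uniform_downstream_p(self, design3):
        """Null phenotype: paired volume comparison p is not systematically
        small over replicates."""
        from medipdmr.phenotype import paired_group_compare, volume_table

        ps = []
        for rep in range(30):
            dia, _ = simulate_phenotypes(
                design3, diameter_mean={"sBF": 85.0, "dBF": 85.0}, seed=rep
            )
            vols = volume_table(dia)
            piv = vols.pivot_table(index="pair_id", columns="group", values="volume_um3")
            ps.append(paired_group_compare(piv["sBF"], piv["dBF"]).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_preset_configurations(self):
        sim10, d10 = preset("eval-n10", seed=3)
        assert d10.n_pairs == 10 and sim10.seed == 3
        _, d3 = preset("study-n3")
        assert d3.n_pairs == 3
        with pytest.raises(ValueError):
            preset("nope")
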