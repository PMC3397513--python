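"""Behaviour of the seed-and-extend DMR caller on constructed inputs."""

import numpy as np
import pytest

from conftest import make_matrix
from medipdmr.core import StudyDesign
from medipdmr.dmr import (
    DMRParams,
    call_dmrs,
    cpg_chain_coverage,
    extend_seed,
    find_seed_cpgs,
    merge_candidates,
    region_significance,
)
from medipdmr.simulate import SimulationParams, simulate_cpg_map, simulate_depth_matrix
from medipdmr.stats import route_test, site_test


def shifted_matrix(design, positions, shifted_rows, factor=4.0, base=30, seed=0):
    """Poisson depths with a multiplicative shift for group A on given rows."""
    rng = np.random.default_rng(seed)
    n = len(positions)
    mean = np.full((n, len(design.sample_ids)), float(base))
    cols_a = design.group_columns(design.group_labels[0])
    for r in shifted_rows:
        mean[r, cols_a] *= factor
    return make_matrix(rng.poisson(mean), positions, design)


class TestSeeds:
    def test_seed_alpha_one_accepts_every_cpg(self, small_study):
        matrix, _ = small_study
        params = DMRParams(seed_alpha=0.999999)
        seeds, pvals = find_seed_cpgs(matrix, params)
        expected = np.nonzero(pvals < params.seed_alpha)[0]
        assert np.array_equal(seeds, expected)
        assert seeds.size > 0.95 * matrix.n_cpgs

    def test_strongly_shifted_cpg_is_a_seed(self, design10):
        matrix = shifted_matrix(design10, [100, 200, 300], [1], factor=5.0)
        seeds, _ = find_seed_cpgs(matrix, DMRParams())
        assert 1 in seeds

    def test_seeds_in_genomic_order_with_pvalues(self, small_study):
        matrix, _ = small_study
        seeds, pvals = find_seed_cpgs(matrix, DMRParams())
        assert np.all(np.diff(seeds) > 0)
        assert np.all(pvals[seeds] < 0.01)


class TestExtension:
    def test_gap_over_200_gives_singleton(self, design10):
        matrix = shifted_matrix(design10, [1000, 1201, 1402], [0, 1, 2], factor=5.0)
        region = extend_seed(0, matrix, DMRParams())
        assert region.rows == (0,)

    def test_last_cpg_on_chromosome_is_singleton(self, design10):
        matrix = shifted_matrix(design10, [100, 200, 300], [2], factor=5.0)
        region = extend_seed(2, matrix, DMRParams())
        assert region.rows == (2,)

    def test_six_tight_shifted_cpgs_all_join_with_step_replay(self, design10):
        positions = [1000 + 50 * i for i in range(6)] + [1550 + 300]
        matrix = shifted_matrix(design10, positions, list(range(6)), factor=4.0, seed=3)
        params = DMRParams()
        region = extend_seed(0, matrix, params)
        assert region.rows == (0, 1, 2, 3, 4, 5)
        # step-replay oracle: independently re-run the incorporation rule
        members = [0]
        for nxt in range(1, 6):
            a, b = matrix.group_depths(np.array(members + [nxt]))
            ma, mb = a.mean(axis=0), b.mean(axis=0)
            p = site_test(ma, mb, route_test(ma, mb))
            assert p < params.region_alpha
            members.append(nxt)
        a, b = matrix.group_depths(np.array(members))
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        assert region.p_value == pytest.approx(
            site_test(ma, mb, route_test(ma, mb)), abs=1e-12
        )
        # interval spans first to last member CpG plus the dinucleotide
        assert region.start == 1000 and region.end == 1250 + 2

    def test_extension_rejects_non_seed(self, small_study):
        matrix, _ = small_study
        _, pvals = find_seed_cpgs(matrix, DMRParams())
        not_seed = int(np.argmax(pvals))
        with pytest.raises(ValueError):
            extend_seed(not_seed, matrix, DMRParams(), pvals)


class TestMerge:
    def test_empty_list(self, small_study):
        matrix, _ = small_study
        assert merge_candidates([], matrix, DMRParams()) == []

    def test_disjoint_regions_unchanged(self, design10):
        positions = [100, 150, 1000, 1050]
        matrix = shifted_matrix(design10, positions, [0, 1, 2, 3], factor=4.0)
        params = DMRParams()
        r1 = extend_seed(0, matrix, params)
        r2 = extend_seed(2, matrix, params)
        merged = merge_candidates([r1, r2], matrix, params)
        assert [m.rows for m in merged] == [r1.rows, r2.rows]

    def test_overlapping_regions_union_with_recomputed_p(self, design10):
        positions = [100, 150, 200, 250]
        matrix = shifted_matrix(design10, positions, [0, 1, 2, 3], factor=4.0, seed=5)
        params = DMRParams()
        r1 = extend_seed(0, matrix, params)
        r2 = extend_seed(1, matrix, params)
        assert set(r1.rows) & set(r2.rows)
        merged = merge_candidates([r1, r2], matrix, params)
        assert len(merged) == 1
        union = tuple(sorted(set(r1.rows) | set(r2.rows)))
        assert merged[0].rows == union
        a, b = matrix.group_depths(np.array(union))
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        assert merged[0].p_value == pytest.approx(
            site_test(ma, mb, route_test(ma, mb)), abs=1e-12
        )


class TestPermutation:
    def test_identical_groups_give_p_one(self, design10):
        rng = np.random.default_rng(0)
        base = rng.poisson(30, size=(3, 10))
        depths = np.empty((3, 20), dtype=int)
        ca = design10.group_columns(design10.group_labels[0])
        cb = design10.group_columns(design10.group_labels[1])
        depths[:, ca] = base
        depths[:, cb] = base  # within-pair differences all zero
        matrix = make_matrix(depths, [100, 150, 200], design10)
        from medipdmr.dmr import CandidateRegion
        from medipdmr.stats import TestChoice, PARAMETRIC

        r = CandidateRegion("chr1", 100, 202, (0, 1, 2), 1.0, TestChoice(PARAMETRIC, 0, 1))
        p, fb = region_significance([r], matrix, DMRParams())
        assert not fb[0]
        assert p[0] == pytest.approx(1.0)

    def test_three_pairs_fall_back_to_analytic(self, design3):
        rng = np.random.default_rng(1)
        matrix = make_matrix(
            rng.poisson(30, size=(3, 6)), [100, 150, 200], design3
        )
        params = DMRParams()
        from medipdmr.dmr import _routed_region_test, CandidateRegion

        p_region, choice, _, _ = _routed_region_test(matrix, (0, 1, 2), params)
        r = CandidateRegion("chr1", 100, 202, (0, 1, 2), p_region, choice)
        # 2^3 = 8 distinct within-pair relabelings < 10 → analytic p, flagged
        p, fb = region_significance([r], matrix, params)
        assert fb[0]
        assert p[0] == pytest.approx(p_region)

    def test_monte_carlo_agrees_with_exhaustive_sign_flips(self, design10):
        matrix = shifted_matrix(design10, [100, 150, 200], [0, 1, 2], factor=2.0, seed=9)
        params = DMRParams(n_permutations=1000, rng_seed=4)
        from medipdmr.dmr import _routed_region_test, CandidateRegion

        p_region, choice, ma, mb = _routed_region_test(matrix, (0, 1, 2), params)
        r = CandidateRegion("chr1", 100, 202, (0, 1, 2), p_region, choice)
        p, fb = region_significance([r], matrix, params)
        assert not fb[0]
        # exhaustive enumeration over all 2^10 within-pair label swaps
        d = ma - mb
        n = d.size
        obs = abs(d.mean() / (d.std(ddof=1) / np.sqrt(n)))
        hits = 0
        for mask in range(1 << n):
            signs = np.array([1.0 if mask >> i & 1 else -1.0 for i in range(n)])
            f = d * signs
            t = f.mean() / (f.std(ddof=1) / np.sqrt(n))
            hits += abs(t) >= obs - 1e-12
        exact = hits / (1 << n)
        assert p[0] == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / 1000) + 2e-3)


class TestCallDMRs:
    def test_null_simulation_yields_no_dmrs(self, design10):
        params = SimulationParams(n_chroms=1, n_cpgs=1000, effect_size=1.0, seed=21)
        cpg_map = simulate_cpg_map(params)
        matrix, truth = simulate_depth_matrix(cpg_map, design10, params)
        assert len(truth) == 0
        assert call_dmrs(matrix) == []

    def test_planted_window_recovered_with_direction(self, design10):
        # 8-CpG window with a 3-fold elevation in group A, flanked by far CpGs
        positions = [50] + [1000 + 60 * i for i in range(8)] + [3000]
        matrix = shifted_matrix(design10, positions, list(range(1, 9)), factor=3.0, seed=13)
        dmrs = call_dmrs(matrix, DMRParams(rng_seed=13))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.start < 1000 + 60 * 7 and d.end > 1000
        assert d.direction == design10.group_labels[0]
        assert d.q_value < 0.01 and d.n_sig_cpgs >= 5

    def test_four_significant_cpgs_are_not_enough(self, design10):
        positions = [1000 + 60 * i for i in range(4)]
        matrix = shifted_matrix(design10, positions, [0, 1, 2, 3], factor=5.0, seed=17)
        assert call_dmrs(matrix, DMRParams(rng_seed=17)) == []

    def test_gap_rule_holds_on_every_output(self, small_study):
        matrix, _ = small_study
        params = DMRParams(rng_seed=2)
        chrom_pos = matrix.cpg_map.positions
        slices = matrix.cpg_map.row_slices()
        for d in call_dmrs(matrix, params):
            pos = chrom_pos[d.chrom]
            sl = slices[d.chrom]
            member_pos = pos[[r - sl.start for r in d.rows]]
            assert np.all(np.diff(member_pos) <= params.max_gap)

    def test_label_swap_flips_every_direction(self, small_study):
        matrix, _ = small_study
        from medipdmr.core import DepthMatrix

        params = DMRParams(rng_seed=3)
        dmrs = call_dmrs(matrix, params)
        swapped = DepthMatrix(matrix.cpg_map, matrix.depths, matrix.design.swap_groups())
        dmrs_sw = call_dmrs(swapped, params)
        assert [d.rows for d in dmrs] == [d.rows for d in dmrs_sw]
        assert len(dmrs) > 0
        for d, s in zip(dmrs, dmrs_sw):
            assert d.direction != s.direction
            assert d.q_value == pytest.approx(s.q_value)

    def test_column_order_permutation_is_invariant(self, small_study):
        matrix, _ = small_study
        from medipdmr.core import DepthMatrix, StudyDesign

        params = DMRParams(rng_seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(matrix.design.sample_ids))
        design_p = StudyDesign(
            tuple(matrix.design.sample_ids[i] for i in perm),
            tuple(matrix.design.groups[i] for i in perm),
            tuple(matrix.design.pair_ids[i] for i in perm),
        )
        shuffled = DepthMatrix(matrix.cpg_map, matrix.depths[:, perm], design_p)
        dmrs_a = call_dmrs(matrix, params)
        dmrs_b = call_dmrs(shuffled, params)
        assert [(d.rows, d.direction) for d in dmrs_a] == [
            (d.rows, d.direction) for d in dmrs_b
        ]
        for a, b in zip(dmrs_a, dmrs_b):
            assert a.p_value == pytest.approx(b.p_value)


class TestChainCoverage:
    def test_uniform_tight_spacing_fully_covered(self):
        from medipdmr.core import CpGMap

        cm = CpGMap({"chr1": np.arange(0, 500, 50)}, {"chr1": 1000})
        assert cpg_chain_coverage(cm, 200) == 1.0

    def test_uniform_sparse_spacing_uncovered(self):
        from medipdmr.core import CpGMap

        cm = CpGMap({"chr1": np.arange(0, 3000, 300)}, {"chr1": 5000})
        assert cpg_chain_coverage(cm, 200) == 0.0

    def test_hand_placed_mixture(self):
        from medipdmr.core import CpGMap

        # gaps: 100,100,500,50,500,500,100,150,700 → covered sites by hand:
        # 0,1,2 (chain), 3,4 (50 apart), 6,7,8 (chain of 100/150); 5 and 9 isolated
        pos = np.cumsum([10, 100, 100, 500, 50, 500, 500, 100, 150, 700])
        cm = CpGMap({"chr1": pos}, {"chr1": int(pos[-1]) + 10})
        assert cpg_chain_coverage(cm, 200) == pytest.approx(8 / 10)
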