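import itertools

import numpy as np
import pytest
from scipy import stats

from loopforge.integrate import (
    GeneExpression, anchor_ctcf_enrichment, anchor_overlap_stats,
    assign_genes_to_loops, chi_square_2x2, classify_ep_loops,
    convergent_motif_pairs, fpkm, gene_loop_contingency, rank_group_test,
    rank_split,
)
from loopforge.intervals import GenomicInterval, GeneModel, MotifSite, Peak
from loopforge.loops import LoopCall, LoopSet
from loopforge.simulate import SimulationConfig, simulate_loop_coupling

RES = 25_000


def mk_loop(i, j, res=RES):
    return LoopCall("c", GenomicInterval("c", i * res, (i + 1) * res),
                    GenomicInterval("c", j * res, (j + 1) * res),
                    res, (i, j), {"called": 1.0})


def mk_gene(gid, tss, fpkms=(1.0, 1.0), log2fc=0.0, q=1.0):
    return GeneExpression(GeneModel(gid, "c", "+", tss, 2000),
                          {"Control": fpkms[0], "KO": fpkms[1]}, log2fc, q)


class TestFpkm:
    def test_closed_form(self):
        assert fpkm(100, 2000, 10_000_000) == pytest.approx(5.0)

    def test_zero_pairs(self):
        assert fpkm(0, 2000, 10_000_000) == 0.0

    def test_homogeneity_in_total(self, rng):
        for _ in range(20):
            pairs = float(rng.integers(1, 1000))
            length = int(rng.integers(200, 10_000))
            total = int(rng.integers(10 ** 5, 10 ** 8))
            assert fpkm(pairs, length, 2 * total) == pytest.approx(
                fpkm(pairs, length, total) / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fpkm(1, 0, 100)
        with pytest.raises(ValueError):
            fpkm(1, 100, 0)


class TestAnchorOverlap:
    def test_manual_enumeration_fixture(self):
        loops = LoopSet([mk_loop(0, 10), mk_loop(2, 12), mk_loop(4, 14),
                         mk_loop(6, 16), mk_loop(8, 18)])
        peaks = [Peak(GenomicInterval("c", b * RES + 100, b * RES + 300))
                 for b in (0, 10, 2, 4, 14, 8)]  # loops 0,2 fully covered; 1,3,4 partial/none
        out = anchor_overlap_stats(loops, peaks)
        assert out["count"] == 2
        assert out["percent"] == 40.0

    def test_percentage_rounding_to_one_decimal(self):
        loops = LoopSet([mk_loop(10 * k, 10 * k + 5) for k in range(3)])
        peaks = [Peak(GenomicInterval("c", 0, 300 * RES))]
        assert anchor_overlap_stats(loops, peaks)["percent"] == 100.0

    def test_zero_overlap(self):
        loops = LoopSet([mk_loop(0, 10)])
        out = anchor_overlap_stats(loops, [Peak(GenomicInterval("c", 10 ** 8, 10 ** 8 + 10))])
        assert out["percent"] == 0.0

    def test_empty_loop_set_rejected(self):
        with pytest.raises(ValueError):
            anchor_overlap_stats(LoopSet([]), [])


class TestConvergentMotifs:
    def site(self, pos, strand):
        return MotifSite(GenomicInterval("c", pos, pos + 19), strand)

    def test_convergent_pair(self):
        loop = mk_loop(0, 10)
        ok, n = convergent_motif_pairs(loop, [self.site(100, "+"),
                                              self.site(10 * RES + 100, "-")])
        assert ok and n == 1

    def test_divergent_orientation_rejected(self):
        loop = mk_loop(0, 10)
        ok, _ = convergent_motif_pairs(loop, [self.site(100, "-"),
                                              self.site(10 * RES + 100, "+")])
        assert not ok

    def test_pair_count_is_product(self):
        loop = mk_loop(0, 10)
        sites = [self.site(100, "+"), self.site(200, "+")]
        sites += [self.site(10 * RES + k * 100, "-") for k in range(3)]
        ok, n = convergent_motif_pairs(loop, sites)
        assert ok and n == 6


class TestAnchorEnrichment:
    def test_double_fragments_double_fc(self):
        loop = mk_loop(0, 10)
        frags = {"Control": [GenomicInterval("c", 100, 300)] * 10,
                 "KO": [GenomicInterval("c", 100, 300)] * 20}
        out = anchor_ctcf_enrichment(loop, frags,
                                     {"Control": 10 ** 6, "KO": 10 ** 6})
        assert out["fc"] == pytest.approx((20 + 0.5) / (10 + 0.5))

    def test_no_fragments_gives_fc_one(self):
        loop = mk_loop(0, 10)
        out = anchor_ctcf_enrichment(loop, {"Control": [], "KO": []},
                                     {"Control": 10 ** 6, "KO": 10 ** 6})
        assert out["fc"] == 1.0

    def test_counts_match_brute_force(self, rng):
        loop = mk_loop(3, 40)
        frags = [GenomicInterval("c", int(s), int(s) + 200)
                 for s in rng.integers(0, 50 * RES, 500)]
        out = anchor_ctcf_enrichment(loop, {"Control": frags},
                                     {"Control": 10 ** 6})
        oracle = sum(1 for f in frags
                     if f.overlaps(loop.anchor1) or f.overlaps(loop.anchor2))
        assert out["enrichment"]["Control"] == pytest.approx(oracle)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            anchor_ctcf_enrichment(mk_loop(0, 10), {"Control": []},
                                   {"Control": 0})


class TestAssignGenes:
    def test_tss_near_anchor_edge_is_anchored(self):
        loops = LoopSet([mk_loop(4, 40)])
        g = mk_gene("g1", 4 * RES - 500)  # 500 bp upstream of anchor start
        (link,) = assign_genes_to_loops([g], loops)
        assert link.linkage == "anchored"

    def test_tss_beyond_promoter_window_is_outside(self):
        loops = LoopSet([mk_loop(4, 40)])
        g = mk_gene("g1", 4 * RES - 1001)
        (link,) = assign_genes_to_loops([g], loops)
        assert link.linkage == "outside"

    def test_gene_bridging_two_loops_gets_two_links(self):
        loops = LoopSet([mk_loop(4, 40), mk_loop(4, 80)])
        g = mk_gene("g1", 4 * RES + 100)
        links = assign_genes_to_loops([g], loops)
        assert len(links) == 2
        assert all(l.linkage == "anchored" for l in links)


class TestRankSplit:
    @pytest.mark.parametrize("n,k,expected_sizes", [
        (5027, 4, [1257, 1257, 1257, 1256]),
        (2359, 4, [590, 590, 590, 589]),
        (4, 4, [1, 1, 1, 1]),
    ])
    def test_near_equal_sizes(self, n, k, expected_sizes, rng):
        g = rank_split(rng.normal(size=n), k)
        sizes = [len(g.group_indices(i)) for i in range(k)]
        assert sizes == expected_sizes

    def test_groups_are_value_ordered(self, rng):
        v = rng.normal(size=101)
        g = rank_split(v, 4)
        maxes = [v[g.group_indices(i)].max() for i in range(4)]
        mins = [v[g.group_indices(i)].min() for i in range(4)]
        assert all(maxes[i] <= mins[i + 1] for i in range(3))

    def test_partition_and_size_invariant(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 10_000))
            k = int(rng.integers(2, 10))
            g = rank_split(rng.normal(size=n), k)
            sizes = [len(g.group_indices(i)) for i in range(k)]
            assert sum(sizes) == n
            assert all(abs(s - n / k) <= 1 for s in sizes)

    def test_deterministic_under_ties(self):
        v = [1.0] * 8
        g1 = rank_split(v, 4, tiebreak=range(8))
        g2 = rank_split(v, 4, tiebreak=range(8))
        np.testing.assert_array_equal(g1.group_of, g2.group_of)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            rank_split([1.0, 2.0], 4)


def mw_permutation_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)
    def u_stat(a, b):
        return sum(1 for xi in a for yi in b if xi > yi) \
            + 0.5 * sum(1 for xi in a for yi in b if xi == yi)
    u_obs = u_stat(x, y)
    n_total = 0
    n_extreme = 0
    mean_u = n1 * len(y) / 2
    for combo in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(a, b)
        n_total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


class TestRankGroupTest:
    def test_separated_groups_exact_p(self):
        # {1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1
        p = stats.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided",
                               method="exact").pvalue
        assert p == pytest.approx(0.1)
        assert mw_permutation_oracle([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (5, 5), (3, 7), (2, 8)])
    def test_matches_permutation_enumeration(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + 0.5
        p_impl = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="exact").pvalue
        p_oracle = mw_permutation_oracle(list(x), list(y))
        assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_identical_distributions_not_significant(self, rng):
        base = rng.normal(size=40)
        grouping = rank_split(rng.permutation(40).astype(float), 2)
        out = rank_group_test(grouping, base)
        assert out[1]["p"] > 0.05 or np.isnan(out[1]["p"])

    def test_planted_coupling_recovered_at_scale(self):
        # 5027 loops with gamma = 0.5 coupling: medians rise monotonically
        # over CTCF-FC ranks and rank 4 separates sharply from rank 1
        ctcf_fc, loop_fc = simulate_loop_coupling(
            5027, gamma=0.5, sigma=0.2, rng=np.random.default_rng(42))
        grouping = rank_split(ctcf_fc, 4)
        out = rank_group_test(grouping, np.log2(loop_fc))
        medians = [g["median"] for g in out]
        assert medians == sorted(medians)
        assert out[-1]["p"] < 0.01

    def test_external_baseline_reported_as_rank_zero(self, rng):
        grouping = rank_split(rng.normal(size=40), 4)
        out = rank_group_test(grouping, rng.normal(size=40),
                              baseline_values=rng.normal(size=25))
        assert out[0]["group"] == 0 and out[0]["n"] == 25
        assert len(out) == 5


class TestContingency:
    def test_printed_style_table_matches_formula_oracle(self, rng):
        for _ in range(10):
            table = rng.integers(5, 300, size=(2, 2)).astype(float)
            chi2, p = chi_square_2x2(table)
            rows, cols = table.sum(1), table.sum(0)
            E = np.outer(rows, cols) / table.sum()
            oracle = ((table - E) ** 2 / E).sum()
            np.testing.assert_allclose(chi2, oracle, rtol=1e-10)
            np.testing.assert_allclose(p, stats.chi2.sf(oracle, 1), rtol=1e-10)

    def test_symmetric_table_zero(self):
        chi2, p = chi_square_2x2([[50, 50], [50, 50]])
        assert chi2 == 0.0 and p == 1.0

    def test_doubling_doubles_statistic(self, rng):
        t = rng.integers(10, 200, size=(2, 2)).astype(float)
        c1, _ = chi_square_2x2(t)
        c2, _ = chi_square_2x2(2 * t)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-10)

    def test_gene_loop_contingency_counts(self):
        loops = LoopSet([mk_loop(4, 40)])
        genes = [
            mk_gene("up_in", 4 * RES + 10, log2fc=1.0, q=0.01),
            mk_gene("down_in", 40 * RES + 10, log2fc=-1.0, q=0.01),
            mk_gene("up_out", 10 ** 7, log2fc=1.0, q=0.01),
            mk_gene("down_out", 10 ** 7 + 50_000, log2fc=-2.0, q=0.001),
            mk_gene("not_de_exact_q", 10 ** 7 + 90_000, log2fc=2.0, q=0.05),
        ]
        links = assign_genes_to_loops(genes, loops)
        out = gene_loop_contingency(links, de_q_threshold=0.05)
        assert out["table"] == [[1, 1], [1, 1]]  # q = 0.05 exactly is not DE


class TestEpLoops:
    GENES = [GeneModel("g", "c", "+", 40 * RES + 100, 2000)]

    def test_enhancer_promoter_loop_flagged(self):
        loops = LoopSet([mk_loop(4, 40)])
        enh = [GenomicInterval("c", 4 * RES + 10, 4 * RES + 2000)]
        assert classify_ep_loops(loops, enh, self.GENES) == [True]

    def test_promoter_promoter_not_ep(self):
        genes = self.GENES + [GeneModel("g2", "c", "+", 4 * RES + 100, 2000)]
        loops = LoopSet([mk_loop(4, 40)])
        assert classify_ep_loops(loops, [], genes) == [False]

    def test_enhancer_inside_promoter_window_takes_promoter_precedence(self):
        loops = LoopSet([mk_loop(4, 40)])
        # enhancer overlapping the promoter window at anchor2: not an enhancer
        enh = [GenomicInterval("c", 40 * RES + 50, 40 * RES + 500)]
        assert classify_ep_loops(loops, enh, self.GENES) == [False]
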