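import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopforge.intervals import (
    BedParseError, GenomicInterval, GeneModel, Peak,
    annotate_peak, merge_condition_peaks, overlap_query,
    read_bed, read_bedpe, write_bed, write_bedpe,
)


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestBedIO:
    def test_read_maps_fields(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tp1\t5.0\n")
        peaks = read_bed(p)
        assert peaks[0].interval == GenomicInterval("chr1", 100, 200)
        assert peaks[0].id == "p1"
        assert peaks[0].signal_by_condition["signal"] == 5.0

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert read_bed(p) == []

    def test_invalid_interval_reports_line(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t100\t200\n" "chr1\t200\t100\n")
        with pytest.raises(BedParseError, match=":2:"):
            read_bed(p)

    def test_round_trip(self, tmp_path):
        peaks = [
            Peak(GenomicInterval("chr1", 0, 50), "a", {"signal": 1.5}),
            Peak(GenomicInterval("chr1", 60, 90), "b", {"signal": 0.0}),
            Peak(GenomicInterval("chr2", 5, 25), ".", {"signal": 2.0}),
        ]
        path = tmp_path / "rt.bed"
        write_bed(peaks, path)
        again = read_bed(path)
        assert [(p.interval, p.id, p.signal_by_condition) for p in again] == [
            (p.interval, p.id, p.signal_by_condition) for p in peaks]
        # writer is byte-stable on its own canonical output
        path2 = tmp_path / "rt2.bed"
        write_bed(again, path2)
        assert path.read_text() == path2.read_text()

    def test_peak_without_id_written_as_dot(self, tmp_path):
        path = tmp_path / "dot.bed"
        write_bed([Peak(GenomicInterval("chr1", 0, 10))], path)
        assert path.read_text().split("\t")[3].strip() == "."


class TestBedpe:
    def test_cis_record_normalized(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t5000\t6000\tchr1\t1000\t2000\n")
        (a, b, _extra), = read_bedpe(p)
        assert a.start == 1000 and b.start == 5000

    def test_trans_record_rejected(self, tmp_path):
        p = tmp_path / "t.bedpe"
        p.write_text("chr1\t0\t10\tchr2\t0\t10\n")
        with pytest.raises(BedParseError, match="cis-only"):
            read_bedpe(p)

    def test_round_trip(self, tmp_path):
        recs = [(GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 50, 60),
                 ["x", "1.5"])]
        path = tmp_path / "rt.bedpe"
        write_bedpe(recs, path)
        assert read_bedpe(path) == recs


class TestOverlapQuery:
    def test_half_open_boundary(self):
        a = [GenomicInterval("c", 0, 10)]
        b = [GenomicInterval("c", 10, 20), GenomicInterval("c", 9, 20)]
        assert overlap_query(a, b) == [(0, 1)]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        def mk(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 500))
                out.append(GenomicInterval(
                    "chr" + str(rng.integers(1, 3)), s, s + int(rng.integers(1, 60))))
            return out
        A, B = mk(50), mk(50)
        expected = sorted(
            (i, j) for i, a in enumerate(A) for j, b in enumerate(B)
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end)
        assert overlap_query(A, B) == expected

    def test_symmetric_in_arguments(self, rng):
        A = [GenomicInterval("c", int(s), int(s) + 10)
             for s in rng.integers(0, 200, 20)]
        B = [GenomicInterval("c", int(s), int(s) + 10)
             for s in rng.integers(0, 200, 20)]
        assert sorted((j, i) for i, j in overlap_query(A, B)) == overlap_query(B, A)


class TestMergeConditionPeaks:
    def test_overlapping_pair_merges_to_union(self):
        c = [Peak(GenomicInterval("c", 100, 200), "a", {"Control": 1.0})]
        k = [Peak(GenomicInterval("c", 150, 250), "b", {"KO": 2.0})]
        (m,) = merge_condition_peaks(c, k)
        assert (m.interval.start, m.interval.end) == (100, 250)
        assert m.signal_by_condition == {"Control": 1.0, "KO": 2.0}

    def test_disjoint_peaks_fill_missing_condition_with_zero(self):
        c = [Peak(GenomicInterval("c", 0, 10), "a", {"Control": 1.0})]
        k = [Peak(GenomicInterval("c", 100, 110), "b", {"KO": 2.0})]
        m = merge_condition_peaks(c, k)
        assert len(m) == 2
        assert m[0].signal_by_condition == {"Control": 1.0, "KO": 0.0}
        assert m[1].signal_by_condition == {"Control": 0.0, "KO": 2.0}

    def test_transitive_chain_collapses(self):
        c = [Peak(GenomicInterval("c", 0, 10)), Peak(GenomicInterval("c", 18, 30))]
        k = [Peak(GenomicInterval("c", 8, 20))]
        (m,) = merge_condition_peaks(c, k)
        assert (m.interval.start, m.interval.end) == (0, 30)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_components_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = []
        for _ in range(30):
            s = int(rng.integers(0, 300))
            ivs.append(GenomicInterval("c", s, s + int(rng.integers(1, 40))))
        half = len(ivs) // 2
        merged = merge_condition_peaks(
            [Peak(iv) for iv in ivs[:half]], [Peak(iv) for iv in ivs[half:]])
        # union-find oracle over the overlap graph
        parent = list(range(len(ivs)))
        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                if ivs[i].overlaps(ivs[j]):
                    parent[find(j)] = find(i)
        comps = {}
        for i, iv in enumerate(ivs):
            comps.setdefault(find(i), []).append(iv)
        expected = sorted((min(x.start for x in c), max(x.end for x in c))
                          for c in comps.values())
        assert sorted((m.interval.start, m.interval.end) for m in merged) == expected

    def test_idempotent(self):
        c = [Peak(GenomicInterval("c", 0, 10), "a", {"Control": 1.0}),
             Peak(GenomicInterval("c", 5, 30), "b", {"Control": 2.0})]
        merged = merge_condition_peaks(c, [])
        again = merge_condition_peaks(merged, [])
        assert [(m.interval.start, m.interval.end, m.signal_by_condition)
                for m in merged] == \
               [(m.interval.start, m.interval.end, m.signal_by_condition)
                for m in again]


class TestAnnotatePeak:
    GENES = [GeneModel("g1", "c", "+", 10_000, 5_000),
             GeneModel("g2", "c", "-", 50_000, 8_000)]

    def test_promoter_takes_precedence(self):
        p = Peak(GenomicInterval("c", 9_950, 10_050))
        assert annotate_peak(p, self.GENES) == "promoter-TSS"

    def test_gene_body_is_genic(self):
        p = Peak(GenomicInterval("c", 13_000, 13_200))  # 3 kb into g1 body
        assert annotate_peak(p, self.GENES) == "genic"

    def test_gene_free_region_is_intergenic(self):
        p = Peak(GenomicInterval("c", 200_000, 200_100))
        assert annotate_peak(p, self.GENES) == "intergenic"

    def test_minus_strand_tss_is_gene_end(self):
        # g2 is minus strand: TSS at 50 kb, body upstream [42 kb, 50 kb)
        assert annotate_peak(Peak(GenomicInterval("c", 50_500, 50_900)),
                             self.GENES) == "promoter-TSS"
        assert annotate_peak(Peak(GenomicInterval("c", 45_000, 45_100)),
                             self.GENES) == "genic"
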