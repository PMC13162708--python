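import math

import pytest

from conslift.classify import ConstraintCategory
from conslift.intervals import GenomicInterval, TEInterval
from conslift.overlaps import (
    OVERALL,
    attribute_te_classes,
    merge_spans,
    motif_reports,
    qtl_overlap,
    te_class_composition,
    te_coverage,
)

from .helpers import brute_covered_bases, brute_overlap_pairs, random_intervals

C = ConstraintCategory


def te(seq, start, end, cls, name="te"):
    return TEInterval(seq, start, end, ".", name, te_class=cls, te_family="")


class TestTeCoverage:
    def test_no_tes(self):
        r = te_coverage([GenomicInterval("chr1", 0, 100, ".", "a")], [])
        assert r.per_category[OVERALL].coverage_fraction == 0.0

    def test_full_coverage(self):
        r = te_coverage([GenomicInterval("chr1", 0, 100, ".", "a")],
                        [te("chr1", 0, 100, "LINE")])
        assert r.per_category[OVERALL].coverage_fraction == 1.0

    def test_overlapping_tes_merged(self):
        # [10,30) u [20,50) = [10,50): 40 bases of a 100-base RE
        r = te_coverage([GenomicInterval("chr1", 0, 100, ".", "a")],
                        [te("chr1", 10, 30, "LINE"), te("chr1", 20, 50, "SINE")])
        assert r.per_category[OVERALL].te_covered_bases == 40
        assert r.per_category[OVERALL].coverage_fraction == 0.40

    def test_empty_res_rejected(self):
        with pytest.raises(ValueError):
            te_coverage([], [te("chr1", 0, 10, "LINE")])

    def test_split_te_invariance(self):
        res = [GenomicInterval("chr1", 0, 200, ".", "a")]
        whole = te_coverage(res, [te("chr1", 20, 120, "LINE")])
        split = te_coverage(res, [te("chr1", 20, 70, "LINE"), te("chr1", 70, 120, "LINE")])
        assert whole.per_category[OVERALL].te_covered_bases == \
            split.per_category[OVERALL].te_covered_bases

    def test_merge_idempotent(self):
        tes = [te("chr1", 10, 30, "LINE"), te("chr1", 20, 50, "LINE"),
               te("chr1", 45, 60, "LINE")]
        merged_spans = merge_spans([(t.start, t.end) for t in tes])
        merged = [te("chr1", lo, hi, "LINE") for lo, hi in merged_spans]
        res = [GenomicInterval("chr1", 0, 100, ".", "a")]
        assert te_coverage(res, tes).per_category[OVERALL].te_covered_bases == \
            te_coverage(res, merged).per_category[OVERALL].te_covered_bases


class TestClassComposition:
    def test_single_class(self):
        res = [GenomicInterval("chr1", 0, 100, ".", "a")]
        r = te_class_composition(res, [te("chr1", 10, 20, "LINE")])
        cc = r.per_category[OVERALL]
        assert cc.class_covered_bases == {"LINE": 10}
        assert cc.class_fraction("LINE") == 0.10 and cc.class_fraction("LTR") == 0.0

    def test_longer_element_wins_shared_bases(self):
        # LINE [0,20) vs LTR [10,30) in RE [0,30): equal lengths -> tie ->
        # lexicographic class order gives LINE [0,20), LTR [20,30)
        res = [GenomicInterval("chr1", 0, 30, ".", "a")]
        r = te_class_composition(res, [te("chr1", 0, 20, "LINE"), te("chr1", 10, 30, "LTR")])
        cc = r.per_category[OVERALL]
        assert cc.class_covered_bases == {"LINE": 20, "LTR": 10}
        assert sum(cc.class_covered_bases.values()) == cc.te_covered_bases == 30

    def test_strictly_longer_wins(self):
        res = [GenomicInterval("chr1", 0, 40, ".", "a")]
        r = te_class_composition(res, [te("chr1", 0, 35, "SINE"), te("chr1", 25, 40, "DNA")])
        cc = r.per_category[OVERALL]
        assert cc.class_covered_bases == {"SINE": 35, "DNA": 5}

    def test_unknown_class_counted_as_other(self):
        res = [GenomicInterval("chr1", 0, 100, ".", "a")]
        r = te_class_composition(res, [te("chr1", 0, 10, "Weird")])
        assert r.per_category[OVERALL].class_covered_bases == {"OTHER": 10}

    def test_disjoint_attribution_sums_to_coverage(self, rng):
        res = random_intervals(rng, 30, "chr1", 5000, 50, 200, "re")
        classes = ["LINE", "SINE", "LTR", "DNA", "Satellite"]
        tes = [te("chr1", iv.start, iv.end, classes[i % 5], f"t{i}")
               for i, iv in enumerate(random_intervals(rng, 80, "chr1", 5000, 20, 300))]
        r = te_class_composition(res, tes)
        cc = r.per_category[OVERALL]
        assert sum(cc.class_covered_bases.values()) == cc.te_covered_bases


class TestMotifReports:
    def test_no_hits_undefined_overlap(self):
        res = [GenomicInterval("chr1", 0, 100, ".", "a")]
        r = motif_reports(res, [], [te("chr1", 0, 10, "LINE")])
        assert r.per_category[OVERALL].proportion == 0.0
        assert r.overlap_proportion_in_res is None

    def test_all_hits_in_te(self):
        res = [GenomicInterval("chr1", 0, 100, ".", "a")]
        hits = [GenomicInterval("chr1", 5, 15, ".", "m1")]
        r = motif_reports(res, hits, [te("chr1", 0, 50, "LINE")])
        assert r.overlap_proportion_in_res == 1.0

    def test_enumerated_fixture(self):
        # 10 REs, 4 have hits; 6 in-RE hits, 3 touch TEs -> 0.40 / 0.50
        res = [GenomicInterval("chr1", i * 1000, i * 1000 + 100, ".", f"re{i}")
               for i in range(10)]
        hits = [
            GenomicInterval("chr1", 10, 20, ".", "m0"),        # re0, in TE
            GenomicInterval("chr1", 30, 40, ".", "m1"),        # re0, in TE
            GenomicInterval("chr1", 1_010, 1_020, ".", "m2"),  # re1, in TE
            GenomicInterval("chr1", 2_010, 2_020, ".", "m3"),  # re2
            GenomicInterval("chr1", 3_010, 3_020, ".", "m4"),  # re3
            GenomicInterval("chr1", 3_030, 3_040, ".", "m5"),  # re3
            GenomicInterval("chr1", 500_000, 500_010, ".", "m6"),  # outside REs
        ]
        tes = [te("chr1", 0, 50, "LINE"), te("chr1", 1_000, 1_050, "SINE")]
        r = motif_reports(res, hits, tes)
        assert r.per_category[OVERALL].proportion == 0.40
        assert r.n_motif_hits_in_res == 6
        assert r.overlap_proportion_in_res == 0.50

    def test_random_fixture_matches_brute_force(self, rng):
        res = random_intervals(rng, 100, "chr1", 20_000, 50, 150, "re")
        tes = [te("chr1", iv.start, iv.end, "LINE", iv.name)
               for iv in random_intervals(rng, 200, "chr1", 20_000, 20, 200, "te")]
        hits = random_intervals(rng, 50, "chr1", 20_000, 5, 15, "m")
        r = motif_reports(res, hits, tes)
        with_hit = {a for a, _ in brute_overlap_pairs(res, hits)}
        assert r.per_category[OVERALL].n_res_with_motif == len(with_hit)
        in_re = {b for _, b in brute_overlap_pairs(res, hits)}
        in_te = {b for _, b in brute_overlap_pairs(tes, hits)}
        assert r.n_motif_hits_in_res == len(in_re)
        assert r.n_motif_hits_overlapping_te == len(in_re & in_te)
        assert r.n_all_hits_overlapping_te == len(in_te)


class TestQtlOverlap:
    def test_oversized_qtl_excluded(self):
        res = [GenomicInterval("chr1", 100, 200, ".", "re1")]
        qtls = [GenomicInterval("chr1", 0, 2_000_000, ".", "big")]
        assert qtl_overlap(res, qtls) == []

    def test_exactly_one_mb_kept(self):
        res = [GenomicInterval("chr1", 100, 200, ".", "re1")]
        qtls = [GenomicInterval("chr1", 0, 1_000_000, ".", "q1")]
        assert qtl_overlap(res, qtls) == [("re1", "q1")]

    def test_pair_listed_once(self):
        res = [GenomicInterval("chr1", 0, 1_000, ".", "re1")]
        qtls = [GenomicInterval("chr1", 0, 500, ".", "q1"),
                GenomicInterval("chr1", 400, 900, ".", "q1")]
        assert qtl_overlap(res, qtls) == [("re1", "q1")]

    def test_random_fixture_matches_quadratic_oracle(self, rng):
        res = random_intervals(rng, 5, "chr1", 100_000, 100, 2_000, "re")
        qtls = random_intervals(rng, 3, "chr1", 100_000, 1_000, 50_000, "q")
        got = set(qtl_overlap(res, qtls, max_qtl_len=1_000_000))
        assert got == brute_overlap_pairs(res, qtls)

    def test_larger_fixture_with_filter(self, rng):
        res = random_intervals(rng, 100, "chr1", 5_000_000, 100, 1_000, "re")
        qtls = random_intervals(rng, 20, "chr1", 5_000_000, 500_000, 2_000_000, "q")
        max_len = 1_000_000
        got = set(qtl_overlap(res, qtls, max_len))
        kept = [q for q in qtls if q.length <= max_len]
        assert got == brute_overlap_pairs(res, kept)
        dropped = {q.name for q in qtls if q.length > max_len}
        assert all(b not in dropped for _, b in got)


class TestCoverageInvariants:
    def test_overall_is_length_weighted_mean(self, rng):
        res = random_intervals(rng, 40, "chr1", 10_000, 50, 200, "re")
        tes = [te("chr1", iv.start, iv.end, "LINE", iv.name)
               for iv in random_intervals(rng, 60, "chr1", 10_000, 30, 150, "te")]
        cats = {iv.name: list(C)[i % 4] for i, iv in enumerate(res)}
        r = te_coverage(res, tes, cats)
        total_bases = sum(cc.total_re_bases for k, cc in r.per_category.items() if k != OVERALL)
        covered = sum(cc.te_covered_bases for k, cc in r.per_category.items() if k != OVERALL)
        assert total_bases == r.per_category[OVERALL].total_re_bases
        assert covered == r.per_category[OVERALL].te_covered_bases
        for key, cc in r.per_category.items():
            assert 0.0 <= cc.coverage_fraction <= 1.0

    def test_per_re_coverage_matches_per_base_oracle(self, rng):
        res = random_intervals(rng, 100, "chr1", 20_000, 50, 150, "re")
        tes = [te("chr1", iv.start, iv.end, "LINE", iv.name)
               for iv in random_intervals(rng, 200, "chr1", 20_000, 20, 200, "te")]
        r = te_coverage(res, tes)
        brute = sum(brute_covered_bases(iv, tes) for iv in res)
        assert r.per_category[OVERALL].te_covered_bases == brute
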