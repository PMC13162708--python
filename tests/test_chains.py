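from fractions import Fraction

import numpy as np
import pytest

from conslift.chains import (
    ChainAlignment,
    ChainBlock,
    ChainIndex,
    ChainIntegrityError,
    ConservationMatrix,
    conservation_matrix,
    project_interval,
    read_chain_file,
    write_chain_file,
)
from conslift.intervals import GenomicInterval

from .conftest import make_identity_chain
from .helpers import brute_force_aligned_bases, chain_base_map, invert_chain, random_chain


def two_block_chain(t_start=0, q_start=0, chain_id=1, score=100.0,
                    t_name="chr1", q_strand="+"):
    """Blocks '50 10 0' / '50': 110 source bases, 100 target bases."""
    c = ChainAlignment(score=score, t_name=t_name, t_size=1000, t_strand="+",
                       t_start=t_start, t_end=t_start + 110,
                       q_name="tgt", q_size=1000, q_strand=q_strand,
                       q_start=q_start, q_end=q_start + 100, chain_id=chain_id,
                       blocks=[ChainBlock(50, 10, 0), ChainBlock(50, 0, 0)])
    c.validate()
    return c


class TestReadChainFile:
    def test_identity_chain(self, tmp_path):
        p = tmp_path / "a.chain"
        p.write_text("chain 100 chr1 1000 + 0 100 chrA 1000 + 0 100 1\n100\n\n")
        (c,) = read_chain_file(p)
        assert len(c.blocks) == 1 and c.blocks[0].size == 100
        assert c.t_end - c.t_start == 100

    def test_block_sums_match_header(self, tmp_path):
        # 50 + 10 + 50 = 110 on source, 100 on target
        p = tmp_path / "a.chain"
        p.write_text("chain 100 chr1 1000 + 0 110 chrA 1000 + 0 100 7\n50 10 0\n50\n\n")
        (c,) = read_chain_file(p)
        assert [b.size for b in c.blocks] == [50, 50]

    def test_block_sum_mismatch_names_chain(self, tmp_path):
        p = tmp_path / "a.chain"
        p.write_text("chain 100 chr1 1000 + 0 120 chrA 1000 + 0 100 7\n50 10 0\n50\n\n")
        with pytest.raises(ChainIntegrityError, match="chain 7"):
            read_chain_file(p)

    def test_roundtrip(self, tmp_path, rng):
        chains = [random_chain(rng, "chr1", 2000, chain_id=i + 1) for i in range(20)]
        p = tmp_path / "rt.chain"
        write_chain_file(chains, p)
        assert read_chain_file(p) == chains

    def test_last_block_with_gaps_rejected(self):
        c = ChainAlignment(1, "chr1", 100, "+", 0, 60, "q", 100, "+", 0, 60, 1,
                           blocks=[ChainBlock(60, 5, 5)])
        with pytest.raises(ChainIntegrityError, match="last block"):
            c.validate()


class TestProjectInterval:
    def test_identity_full_fraction(self, identity_index):
        res = project_interval(GenomicInterval("chr1", 100, 200), identity_index)
        assert res.aligned_bases == 100
        assert res.aligned_fraction == 1
        assert res.mapped_segments[0][1] == GenomicInterval("tA.chr1", 100, 200)

    def test_gap_straddling_interval(self):
        # blocks 50 10 0 / 50 at t=0: aligned source bases {0..49} u {60..109}
        index = ChainIndex([two_block_chain()])
        res = project_interval(GenomicInterval("chr1", 40, 70), index)
        assert res.aligned_bases == 20
        assert res.aligned_fraction == Fraction(20, 30)

    def test_uncovered_interval(self):
        index = ChainIndex([two_block_chain()])
        res = project_interval(GenomicInterval("chr1", 500, 600), index)
        assert res.aligned_bases == 0 and res.aligned_fraction == 0
        assert res.mapped_segments == []

    def test_unknown_sequence_fraction_zero(self, identity_index):
        res = project_interval(GenomicInterval("chrZ", 0, 10), identity_index)
        assert res.aligned_fraction == 0

    def test_segment_lengths_sum_to_aligned(self):
        index = ChainIndex([two_block_chain()])
        res = project_interval(GenomicInterval("chr1", 40, 70), index)
        assert sum(seg.length for _, seg, _ in res.mapped_segments) == res.aligned_bases

    def test_minus_strand_coordinates(self):
        chain = two_block_chain(q_strand="-")
        (res,) = [project_interval(GenomicInterval("chr1", 0, 10), ChainIndex([chain]))]
        # per-base oracle: forward target position of source base 0
        expected = dict(chain_base_map(chain))
        seg = res.mapped_segments[0][1]
        assert {expected[t] for t in range(0, 10)} == set(range(seg.start, seg.end))

    def test_overlapping_chains_count_base_once(self):
        c1 = two_block_chain(chain_id=1, score=10)
        c2 = make_identity_chain(chain_id=2, score=99)
        res = project_interval(GenomicInterval("chr1", 40, 70), ChainIndex([c1, c2]))
        assert res.aligned_bases == 30  # identity covers everything, once

    def test_best_mode_uses_best_scoring_chain_only(self):
        weak_full = make_identity_chain(chain_id=1, score=5)
        strong_gappy = two_block_chain(chain_id=2, score=500)
        index = ChainIndex([weak_full, strong_gappy])
        any_res = project_interval(GenomicInterval("chr1", 40, 70), index, mode="any")
        best_res = project_interval(GenomicInterval("chr1", 40, 70), index, mode="best")
        assert any_res.aligned_bases == 30
        assert best_res.aligned_bases == 20


class TestOracleEquivalence:
    def test_index_matches_linear_scan(self, rng):
        chains = [random_chain(rng, "chr1", 3000, chain_id=i + 1) for i in range(1000)]
        index = ChainIndex(chains)
        for _ in range(100):
            start = int(rng.integers(0, 2900))
            end = start + int(rng.integers(1, 100))
            got = {(b.t_start, b.t_end, b.chain_id)
                   for b in index.overlapping_blocks("chr1", start, end)}
            want = set()
            for c in chains:
                for t0, t1, _ in c.block_coordinates():
                    if t0 < end and start < t1:
                        want.add((t0, t1, c.chain_id))
            assert got == want

    def test_projection_matches_per_base_walk(self, rng):
        """>=1000 random intervals over random valid chains, exact equality."""
        chains = [random_chain(rng, "chr1", 2000, chain_id=i + 1) for i in range(120)]
        index = ChainIndex(chains)
        for _ in range(1000):
            start = int(rng.integers(0, 1900))
            end = start + int(rng.integers(1, 100))
            iv = GenomicInterval("chr1", start, end)
            assert project_interval(iv, index).aligned_bases == \
                brute_force_aligned_bases(iv, chains)

    def test_removing_chain_never_increases_fraction(self, rng):
        chains = [random_chain(rng, "chr1", 1000, chain_id=i + 1) for i in range(30)]
        ivs = [GenomicInterval("chr1", int(s), int(s) + 50)
               for s in rng.integers(0, 950, size=40)]
        full = ChainIndex(chains)
        for drop in range(0, 30, 7):
            reduced = ChainIndex(chains[:drop] + chains[drop + 1:])
            for iv in ivs:
                assert project_interval(iv, reduced).aligned_bases <= \
                    project_interval(iv, full).aligned_bases

    def test_split_additivity(self, rng):
        chains = [random_chain(rng, "chr1", 1000, chain_id=i + 1) for i in range(40)]
        index = ChainIndex(chains)
        for _ in range(50):
            start = int(rng.integers(0, 900))
            end = start + int(rng.integers(2, 80))
            mid = int(rng.integers(start + 1, end))
            whole = project_interval(GenomicInterval("chr1", start, end), index)
            left = project_interval(GenomicInterval("chr1", start, mid), index)
            right = project_interval(GenomicInterval("chr1", mid, end), index)
            assert whole.aligned_bases == left.aligned_bases + right.aligned_bases

    def test_minus_strand_round_trip(self, rng):
        """Project through a '-' chain, then through its exact inverse."""
        for i in range(20):
            chain = random_chain(rng, "chr1", 500, chain_id=i + 1)
            if chain.q_strand != "-":
                continue
            index = ChainIndex([chain])
            inv_index = ChainIndex([invert_chain(chain)])
            iv = GenomicInterval("chr1", 0, 500)
            res = project_interval(iv, index)
            recovered = set()
            for _, seg, _ in res.mapped_segments:
                back = project_interval(seg, inv_index)
                for _, back_seg, _ in back.mapped_segments:
                    recovered.update(range(back_seg.start, back_seg.end))
            fwd = dict(chain_base_map(chain))
            assert recovered == set(fwd.keys())


class TestConservationMatrix:
    def test_single_identity_cell(self, identity_index):
        m = conservation_matrix([GenomicInterval("chr1", 0, 10, ".", "RE1")],
                                {"gA": identity_index})
        assert m.shape == (1, 1) and m.exact[0][0] == 1

    def test_missing_locus_column_zero(self, identity_index):
        partial = ChainIndex([make_identity_chain(size=100)])  # covers only [0,100)
        res = [GenomicInterval("chr1", 0, 50, ".", "RE1"),
               GenomicInterval("chr1", 60, 90, ".", "RE2"),
               GenomicInterval("chr1", 500, 600, ".", "RE3")]
        m = conservation_matrix(res, {"gA": identity_index, "gB": partial},
                                genome_order=["gA", "gB"])
        assert m.exact[2][0] == 1 and m.exact[2][1] == 0

    def test_cells_match_brute_force(self, rng):
        genomes = {}
        chain_lists = {}
        for g in range(4):
            chains = [random_chain(rng, "chr1", 2000, chain_id=i + 1) for i in range(50)]
            genomes[f"g{g}"] = ChainIndex(chains)
            chain_lists[f"g{g}"] = chains
        res = [GenomicInterval("chr1", int(s), int(s) + 60, ".", f"RE{i}")
               for i, s in enumerate(rng.integers(0, 1900, size=50))]
        m = conservation_matrix(res, genomes, genome_order=sorted(genomes))
        for i, iv in enumerate(res):
            for j, g in enumerate(m.genome_names):
                assert m.exact[i][j] == Fraction(
                    brute_force_aligned_bases(iv, chain_lists[g]), iv.length)

    def test_duplicate_genome_order_rejected(self, identity_index):
        with pytest.raises(ValueError, match="duplicate"):
            conservation_matrix([GenomicInterval("chr1", 0, 10)],
                                {"gA": identity_index}, genome_order=["gA", "gA"])

    def test_tsv_roundtrip_preserves_exact_decimals(self, tmp_path, identity_index):
        res = [GenomicInterval("chr1", 0, 10, ".", "RE1")]
        m = conservation_matrix(res, {"gA": identity_index})
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = ConservationMatrix.from_tsv(p)
        assert back.re_names == m.re_names
        assert back.genome_names == m.genome_names
        assert back.exact[0][0] == 1

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ConservationMatrix(["a"], ["g"], [[Fraction(3, 2)]])
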