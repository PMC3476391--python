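"""Alignment filtering, edge-trimmed pileups, SNP calls, dedup and rates."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from postkit.config import PipelineConfig
from postkit.snp import (PileupColumn, ReadAlignment, SnpCall, call_snps,
                         dedup_calls, expected_false_snps, filter_alignments,
                         read_alignments_tsv, trim_and_pileup, variant_rate,
                         write_alignments_tsv)


def aln(read_id="r1", isotig="t1", read_start=0, read_len=100, iso_start=0,
        read_aln=None, isotig_aln=None, ident=99.0, e=1e-30, strand="+"):
    if read_aln is None:
        read_aln = "A" * (read_len - read_start)
    if isotig_aln is None:
        isotig_aln = read_aln
    n_read = sum(1 for c in read_aln if c != "-")
    n_iso = sum(1 for c in isotig_aln if c != "-")
    return ReadAlignment(read_id=read_id, isotig_id=isotig,
                         read_start=read_start, read_end=read_start + n_read,
                         isotig_start=iso_start, isotig_end=iso_start + n_iso,
                         read_aln=read_aln, isotig_aln=isotig_aln,
                         read_length=read_len, percent_identity=ident,
                         e_value=e, strand=strand)


GROUPS = {"t1": "ig1", "t2": "ig1", "t3": "ig2"}


class TestFilterAlignments:
    def test_small_overhangs_kept(self):
        # 100 bp read aligned over 1-based read positions 4..97
        a = aln(read_start=3, read_len=100, read_aln="A" * 94)
        assert filter_alignments([a], GROUPS) == [a]

    def test_large_five_prime_overhang_dropped(self):
        # aligned over 1-based positions 10..100: 9 bp unaligned at 5'
        a = aln(read_start=9, read_len=100, read_aln="A" * 91)
        assert filter_alignments([a], GROUPS) == []

    def test_evalue_and_identity_filters(self):
        assert filter_alignments([aln(e=1e-4)], GROUPS) == []
        assert filter_alignments([aln(ident=94.9)], GROUPS) == []
        assert filter_alignments([aln(ident=95.0)], GROUPS) != []

    def test_multi_isogroup_read_dropped_entirely(self):
        a1 = aln(read_id="r9", isotig="t1")
        a2 = aln(read_id="r9", isotig="t3")
        a3 = aln(read_id="r8", isotig="t1")
        kept = filter_alignments([a1, a2, a3], GROUPS)
        assert [a.read_id for a in kept] == ["r8"]

    def test_multi_isotig_same_isogroup_kept(self):
        a1 = aln(read_id="r9", isotig="t1")
        a2 = aln(read_id="r9", isotig="t2")
        assert len(filter_alignments([a1, a2], GROUPS)) == 2

    def test_unknown_isotig_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            filter_alignments([aln(isotig="tX")], {"t1": "ig1"})


class TestTrimAndPileup:
    def test_edge_bases_contribute_nothing(self):
        a = aln(read_len=100, read_aln="C" * 100, isotig_aln="C" * 100)
        cols = {c.position: c for c in trim_and_pileup([a])}
        assert set(cols) == set(range(5, 95))
        assert all(c.depth == 1 for c in cols.values())

    def test_disagreeing_reads_tallied_separately(self):
        a = aln(read_id="r1", read_aln="A" * 20, isotig_aln="A" * 20, read_len=20)
        b = aln(read_id="r2", read_aln="A" * 9 + "G" + "A" * 10,
                isotig_aln="A" * 20, read_len=20)
        cols = {c.position: c for c in trim_and_pileup([a, b])}
        assert cols[9].counts == Counter({"A": 1, "G": 1})

    def test_insertion_consumes_no_isotig_column(self):
        # 3-column toy: read has one inserted base relative to the isotig
        a = aln(read_aln="TTTTTTATTTTTT", isotig_aln="TTTTTT-TTTTTT",
                read_len=13)
        cols = trim_and_pileup([a])
        # untrimmed read positions are 5..7; the inserted base (read pos 6)
        # consumes no column, so only columns 5 and 6 receive bases
        assert {c.position for c in cols} == {5, 6}

    def test_deletion_counts_as_gap_allele(self):
        a = aln(read_aln="TTTTTT-TTTTTT", isotig_aln="TTTTTTCTTTTTT",
                read_len=12)
        cols = {c.position: c for c in trim_and_pileup([a])}
        assert cols[6].counts == Counter({"-": 1})

    def test_reverse_strand_trim_follows_original_read_ends(self):
        # read aligned on '-' strand, 3 bp unaligned at the original 5' end:
        # trimming must remove bases by original read coordinate
        a = aln(read_aln="G" * 17, isotig_aln="G" * 17, read_len=20,
                read_start=0, strand="-")
        a.read_end = 17
        cols = sorted(c.position for c in trim_and_pileup([a]))
        # original-read positions 16..0 map to columns 0..16; positions <5
        # (columns 12..16) and >14 (columns 0..1) are excluded
        assert cols == list(range(2, 12))

    def test_read_order_permutation_invariant(self):
        rng = np.random.default_rng(4)
        alns = [aln(read_id=f"r{i}", read_aln="ACGT" * 10, isotig_aln="ACGT" * 10,
                    read_len=40, iso_start=int(rng.integers(0, 5)))
                for i in range(10)]
        ref = [(c.isotig_id, c.position, c.counts) for c in trim_and_pileup(alns)]
        for _ in range(3):
            rng.shuffle(alns)
            got = [(c.isotig_id, c.position, c.counts)
                   for c in trim_and_pileup(alns)]
            assert got == ref


def col(counts, pos=0, isotig="t1"):
    return PileupColumn(isotig_id=isotig, position=pos, counts=Counter(counts))


class TestCallSnps:
    def test_basic_call(self):
        (c,) = call_snps([col({"A": 7, "G": 3})])
        assert (c.major, c.minor, c.minor_count, c.depth) == ("A", "G", 3, 10)
        assert c.minor_frequency == pytest.approx(0.30)

    def test_frequency_boundary_is_strict(self):
        assert call_snps([col({"A": 12, "G": 3})]) == []   # 3/15 = 0.20 exactly
        assert call_snps([col({"A": 11, "G": 3})]) != []   # 3/14 > 0.20

    def test_support_below_three_rejected(self):
        assert call_snps([col({"A": 5, "G": 2})]) == []

    def test_gap_alleles_ignored(self):
        (c,) = call_snps([col({"A": 5, "-": 4, "G": 3})])
        assert c.depth == 8 and c.minor == "G"
        assert c.minor_frequency == pytest.approx(0.375)

    def test_gap_never_called_even_when_frequent(self):
        assert call_snps([col({"A": 5, "-": 5})]) == []

    @given(st.dictionaries(st.sampled_from("ACGT-"),
                           st.integers(min_value=0, max_value=30),
                           min_size=1))
    @settings(deadline=None, max_examples=200)
    def test_calls_always_satisfy_filters(self, counts):
        calls = call_snps([col(counts)])
        for c in calls:
            assert c.minor_count >= 3
            assert c.minor_frequency > 0.20
            assert c.major in "ACGT" and c.minor in "ACGT" and c.major != c.minor


class TestDedupCalls:
    def _calls(self, n, pos=550, minor_counts=None):
        return [SnpCall(isotig_id=f"t{i:03d}", isogroup_id=None, position=pos,
                        major="G", minor="T",
                        minor_count=minor_counts[i] if minor_counts else 3,
                        depth=10)
                for i in range(n)]

    def test_shared_position_collapses_to_one_unique(self):
        groups = {f"t{i:03d}": "ig18" for i in range(250)}
        out = dedup_calls(self._calls(250), groups)
        assert sum(c.unique for c in out) == 1

    def test_greatest_support_wins(self):
        groups = {f"t{i:03d}": "ig18" for i in range(3)}
        out = dedup_calls(self._calls(3, minor_counts=[3, 7, 5]), groups)
        (u,) = [c for c in out if c.unique]
        assert u.isotig_id == "t001" and u.minor_count == 7

    def test_distinct_contig_positions_stay_unique(self):
        groups = {"t000": "ig1", "t001": "ig1"}
        calls = [SnpCall("t000", None, 550, "G", "T", 3, 10),
                 SnpCall("t001", None, 550, "G", "T", 3, 10)]
        cmap = {("t000", 550): ("cA", 550), ("t001", 550): ("cB", 10)}
        out = dedup_calls(calls, groups, cmap)
        assert sum(c.unique for c in out) == 2

    def test_different_isogroups_never_merged(self):
        groups = {"t000": "ig1", "t001": "ig2"}
        out = dedup_calls(self._calls(2), groups)
        assert all(c.unique for c in out)

    def test_no_two_uniques_share_redundancy_key(self):
        rng = np.random.default_rng(9)
        groups = {f"t{i:03d}": f"ig{i % 3}" for i in range(12)}
        calls = [SnpCall(f"t{int(rng.integers(12)):03d}", None,
                         int(rng.integers(5)), "G", "T",
                         int(rng.integers(3, 9)), 20) for _ in range(80)]
        out = dedup_calls(calls, groups)
        keys = [(c.isogroup_id, c.major, c.minor, c.position)
                for c in out if c.unique]
        assert len(keys) == len(set(keys))


class TestRates:
    def test_published_scale_rate(self):
        assert variant_rate(25_781, int(35.8e6)) == pytest.approx(0.72, abs=0.005)

    def test_degenerate_rates(self):
        assert variant_rate(0, 1000) == 0.0
        assert variant_rate(1, 1000) == 1.0

    def test_expected_false_zero_error(self):
        assert expected_false_snps(0.0, 8, 3) == 0.0

    def test_exact_tail_matches_closed_form(self):
        p = 2.2e-4
        expected = sum(math.comb(8, k) * p ** k * (1 - p) ** (8 - k)
                       for k in range(3, 9))
        got = expected_false_snps(p, 8, 3)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(5.96e-10, rel=0.01)

    def test_monotone_in_min_support(self):
        assert expected_false_snps(2.2e-4, 8, 4) < expected_false_snps(2.2e-4, 8, 3)


class TestAlignmentTsvRoundtrip:
    def test_roundtrip(self, tmp_path):
        alns = [aln(read_id="r1"), aln(read_id="r2", read_aln="ACGTACGTAC",
                                       isotig_aln="ACGTACGTAC", read_len=10)]
        p = tmp_path / "alns.tsv"
        write_alignments_tsv(alns, p)
        back = read_alignments_tsv(p)
        assert [(a.read_id, a.read_aln, a.isotig_start) for a in back] == \
               [(a.read_id, a.read_aln, a.isotig_start) for a in alns]
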