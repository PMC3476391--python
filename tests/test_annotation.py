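"""Top-hit selection, isogroup annotation consolidation, and term joins."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from postkit.annotation import (AnnotationAssignment, LookupTable, SynonymMap,
                                annotation_census, consolidate_isogroup,
                                join_terms, normalize_label, top_hit)
from postkit.io import AlignmentHit
from postkit.isogroup import Isogroup, Isotig


def hit(q, s, bit, e=1e-40, ident=90.0):
    return AlignmentHit(query_id=q, subject_id=s, percent_identity=ident,
                        align_length=100, mismatches=10, gap_opens=0,
                        q_start=1, q_end=100, s_start=1, s_end=100,
                        e_value=e, bit_score=bit)


def group_of(*isotig_ids):
    return Isogroup(id="ig1", contig_ids=set(isotig_ids),
                    isotigs=[Isotig(id=t, contig_ids=[t], length=1)
                             for t in isotig_ids])


class TestTopHit:
    def test_highest_bit_wins(self):
        best = top_hit([hit("q1", "a", 120), hit("q1", "b", 180)], 1e-5)
        assert best["q1"].subject_id == "b"

    def test_evalue_cutoff_is_strict(self):
        assert top_hit([hit("q1", "a", 100, e=1e-4)], 1e-5) == {}
        assert top_hit([hit("q1", "a", 100, e=1e-5)], 1e-5) == {}
        assert "q1" in top_hit([hit("q1", "a", 100, e=0.9e-5)], 1e-5)

    def test_tie_breaks_evalue_then_subject(self):
        best = top_hit([hit("q1", "b", 100, e=1e-20),
                        hit("q1", "a", 100, e=1e-30)], 1e-5)
        assert best["q1"].subject_id == "a"
        best = top_hit([hit("q1", "b", 100, e=1e-30),
                        hit("q1", "a", 100, e=1e-30)], 1e-5)
        assert best["q1"].subject_id == "a"


class TestNormalizeLabel:
    @pytest.mark.parametrize("raw,expected", [
        ("HBB", "hbb"),
        ("PREDICTED: tumor protein p53", "tumor protein p53"),
        ("nebulin-like", "nebulin"),
        ("hypothetical protein ABC_123", "protein abc_123"),
    ])
    def test_examples(self, raw, expected):
        assert normalize_label(raw) == expected


class TestConsolidateIsogroup:
    def test_agreement_gives_single(self):
        hits = {"t1": hit("t1", "P1", 200), "t2": hit("t2", "P1", 150)}
        labels = {"P1": "HBB"}
        a = consolidate_isogroup(group_of("t1", "t2"), hits, SynonymMap(),
                                 subject_labels=labels)
        assert a.status == "single" and a.gene_label == "HBB"

    def test_synonyms_collapse(self):
        hits = {"t1": hit("t1", "P1", 200), "t2": hit("t2", "P2", 150)}
        labels = {"P1": "TP53", "P2": "tumor protein p53"}
        syn = SynonymMap({"tumor protein p53": "TP53"})
        a = consolidate_isogroup(group_of("t1", "t2"), hits, syn,
                                 subject_labels=labels)
        assert a.status == "collapsed_synonym" and a.gene_label == "tp53"

    def test_top5_cumulative_bit_tiebreak(self):
        hits = {"t1": hit("t1", "PA", 200), "t2": hit("t2", "PB", 150)}
        labels = {"PA": "geneA", "PB": "geneB", "PA2": "geneA", "PB2": "geneB"}
        # both geneA and geneB appear in every top-5 list and among originals;
        # cumulative bits: geneA = 160+140 = 300, geneB = 120+120 = 240
        secondary = {
            "t1": [hit("t1", "PA", 160, e=1e-20), hit("t1", "PB", 120, e=1e-20)],
            "t2": [hit("t2", "PA2", 140, e=1e-20), hit("t2", "PB2", 120, e=1e-20)],
        }
        a = consolidate_isogroup(group_of("t1", "t2"), hits, SynonymMap(),
                                 secondary_hits=secondary, subject_labels=labels)
        assert a.status == "resolved_top5" and a.gene_label == "genea"

    def test_secondary_evalue_filter_applies(self):
        hits = {"t1": hit("t1", "PA", 200), "t2": hit("t2", "PB", 150)}
        labels = {"PA": "geneA", "PB": "geneB"}
        # shared candidate fails the strict secondary threshold -> unresolved
        secondary = {"t1": [hit("t1", "PA", 160, e=1e-8)],
                     "t2": [hit("t2", "PA", 140, e=1e-8)]}
        a = consolidate_isogroup(group_of("t1", "t2"), hits, SynonymMap(),
                                 secondary_hits=secondary, subject_labels=labels)
        assert a.status == "unresolved" and a.gene_label is None

    def test_no_common_candidate_unresolved(self):
        hits = {"t1": hit("t1", "PA", 200), "t2": hit("t2", "PB", 150)}
        secondary = {"t1": [hit("t1", "PX", 100, e=1e-20)],
                     "t2": [hit("t2", "PY", 100, e=1e-20)]}
        a = consolidate_isogroup(group_of("t1", "t2"), hits, SynonymMap(),
                                 secondary_hits=secondary)
        assert a.status == "unresolved" and a.gene_label is None

    def test_no_hits_gives_none(self):
        a = consolidate_isogroup(group_of("t1"), {}, SynonymMap())
        assert a.status == "none" and a.gene_label is None

    def test_order_independent(self):
        labels = {"P1": "TP53", "P2": "tumor protein p53", "P3": "TP53"}
        syn = SynonymMap({"tumor protein p53": "TP53"})
        results = set()
        for perm in itertools.permutations(["t1", "t2", "t3"]):
            hits = {t: hit(t, p, 100 + i)
                    for i, (t, p) in enumerate(zip(perm, ["P1", "P2", "P3"]))}
            a = consolidate_isogroup(group_of(*perm), hits, syn,
                                     subject_labels=labels)
            results.add((a.status, a.gene_label))
        assert len(results) == 1

    @given(st.text(alphabet=st.characters(categories=("Lu", "Ll", "Nd")),
                   min_size=1, max_size=12),
           st.integers(min_value=1, max_value=5))
    @settings(deadline=None, max_examples=50)
    def test_agreeing_inputs_always_single(self, label, n_isotigs):
        tids = [f"t{i}" for i in range(n_isotigs)]
        hits = {t: hit(t, "P1", 100) for t in tids}
        a = consolidate_isogroup(group_of(*tids), hits, SynonymMap(),
                                 subject_labels={"P1": label})
        assert a.status == "single"


class TestAnnotationCensus:
    def test_unresolved_counts_as_annotated(self):
        assignments = [
            AnnotationAssignment("g1", "a", "single"),
            AnnotationAssignment("g2", "a", "single"),
            AnnotationAssignment("g3", None, "unresolved"),
        ]
        c = annotation_census(assignments)
        assert c["n_annotated"] == 3 and c["n_labeled"] == 2

    def test_label_multiplicity(self):
        assignments = [AnnotationAssignment(f"g{i}", lab, "single")
                       for i, lab in enumerate(["A", "A", "B"])]
        c = annotation_census(assignments)
        assert c["n_unique_labels"] == 2
        assert c["n_labels_multi_isogroup"] == 1
        assert c["mean_isogroups_per_multi_label"] == 2.0

    def test_empty(self):
        c = annotation_census([])
        assert c["n_annotated"] == 0 and c["n_unique_labels"] == 0


class TestJoinTerms:
    def test_passing_hit_gets_terms(self):
        table = LookupTable({"P1": ["GO:0008150"]})
        terms, excluded = join_terms({"q1": hit("q1", "P1", 100, e=1e-20)},
                                     table, 1e-15)
        assert terms == {"q1": ["GO:0008150"]} and not excluded

    def test_strict_cutoff_blocks(self):
        table = LookupTable({"P1": ["GO:0008150"]})
        terms, _ = join_terms({"q1": hit("q1", "P1", 100, e=1e-12)}, table, 1e-15)
        assert terms == {}

    def test_multi_subject_isogroup_excluded(self):
        table = LookupTable({"P1": ["GO:1"], "P2": ["GO:2"]})
        hits = {"t1": hit("t1", "P1", 100, e=1e-20),
                "t2": hit("t2", "P2", 100, e=1e-20)}
        terms, excluded = join_terms(hits, table, 1e-15,
                                     unit_of={"t1": "ig1", "t2": "ig1"})
        assert excluded == {"ig1"} and terms == {}

    def test_unknown_subject_skipped(self, caplog):
        table = LookupTable({})
        terms, excluded = join_terms({"q1": hit("q1", "P9", 100, e=1e-20)},
                                     table, 1e-15)
        assert terms == {} and not excluded
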