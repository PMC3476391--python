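"""Top-hit annotation assignment and isogroup-level consolidation.

Each isotig or singleton receives the gene label of its best protein hit
(highest bit score below the e-value cutoff).  Because the isotigs of one
isogroup represent splice forms of the same gene, their labels are
consolidated into a single isogroup annotation: exact agreement, synonym
collapsing via a curated synonym table, and — for isogroups whose labels
still disagree — an intersection of the top-five secondary hits per isotig
with a cumulative-bit-score tie-break.  GO / pathway / orthology terms are
joined from lookup tables under per-source e-value cutoffs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import AlignmentHit
from .isogroup import Isogroup

log = logging.getLogger("postkit")

_DROP_TOKENS = {"predicted", "hypothetical"}


def normalize_label(label: str) -> str:
    """Casefold, strip punctuation and the tokens 'predicted'/'hypothetical'/'-like'."""
    s = label.casefold()
    s = re.sub(r"-like\b", " ", s)
    s = re.sub(r"[^\w\s]", " ", s)
    tokens = [t for t in s.split() if t not in _DROP_TOKENS]
    return " ".join(tokens)


class SynonymMap:
    """Mapping from normalized gene label to its canonical label.

    Canonical labels map to themselves, so lookup is idempotent.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for label, canonical in (mapping or {}).items():
            self.add(label, canonical)

    def add(self, label: str, canonical: str) -> None:
        canon_n = normalize_label(canonical)
        self._map[normalize_label(label)] = canon_n
        self._map.setdefault(canon_n, canon_n)

    def canonical(self, label: str) -> str:
        n = normalize_label(label)
        return self._map.get(n, n)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["label", "canonical"],
                         dtype=str)
        m = cls()
        for r in df.itertuples(index=False):
            m.add(r.label, r.canonical)
        return m


@dataclass
class AnnotationAssignment:
    unit_id: str
    gene_label: str | None
    status: str  # single | collapsed_synonym | resolved_top5 | unresolved | none
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.gene_label is None) != (self.status in ("unresolved", "none")):
            raise ValueError(f"{self.unit_id}: gene_label must be null iff status "
                             f"is unresolved/none (got {self.status})")


def _better(a: AlignmentHit, b: AlignmentHit) -> AlignmentHit:
    """Best hit: max bit score, ties -> min e-value, then lexicographic subject."""
    ka = (-a.bit_score, a.e_value, a.subject_id)
    kb = (-b.bit_score, b.e_value, b.subject_id)
    return a if ka <= kb else b


def top_hit(hits: Iterable[AlignmentHit],
            evalue_cutoff: float) -> dict[str, AlignmentHit]:
    """Best passing hit per query (strict e-value inequality)."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        if h.e_value >= evalue_cutoff:
            continue
        cur = best.get(h.query_id)
        best[h.query_id] = h if cur is None else _better(cur, h)
    return best


def consolidate_isogroup(group: Isogroup,
                         per_isotig_hits: Mapping[str, AlignmentHit],
                         synonyms: SynonymMap,
                         secondary_hits: Mapping[str, Sequence[AlignmentHit]] | None = None,
                         subject_labels: Mapping[str, str] | None = None,
                         secondary_evalue: float = 1e-10) -> AnnotationAssignment:
    """Reduce the per-isotig labels of an isogroup to one annotation.

    Resolution ladder: (1) all labels agree -> ``single``; (2) labels differ
    but share one canonical synonym -> ``collapsed_synonym``; (3) a gene
    present in every isotig's top-five secondary hit list (filtered at
    ``secondary_evalue``) and matching an original label -> ``resolved_top5``
    (several candidates: highest cumulative bit score wins); (4) otherwise
    ``unresolved`` with a null label.  Isotigs with no primary hit at all
    yield status ``none``.
    """
    def label_of(hit: AlignmentHit) -> str:
        if subject_labels is not None:
            return subject_labels.get(hit.subject_id, hit.subject_id)
        return hit.subject_id

    isotig_ids = sorted(t.id for t in group.isotigs) if group.isotigs \
        else sorted(group.contig_ids)
    hit_isotigs = [i for i in isotig_ids if i in per_isotig_hits]
    if not hit_isotigs:
        return AnnotationAssignment(group.id, None, "none")

    evidence = [per_isotig_hits[i].subject_id for i in hit_isotigs]
    raw = [normalize_label(label_of(per_isotig_hits[i])) for i in hit_isotigs]
    display = {normalize_label(label_of(per_isotig_hits[i])):
               label_of(per_isotig_hits[i]) for i in hit_isotigs}
    if len(set(raw)) == 1:
        return AnnotationAssignment(group.id, display[raw[0]], "single", evidence)

    canon = [synonyms.canonical(label_of(per_isotig_hits[i])) for i in hit_isotigs]
    if len(set(canon)) == 1:
        return AnnotationAssignment(group.id, canon[0], "collapsed_synonym", evidence)

    # top-5 secondary rescue
    if secondary_hits is not None:
        per_list: list[set[str]] = []
        cum_bits: dict[str, float] = {}
        for i in hit_isotigs:
            hits5 = [h for h in secondary_hits.get(i, ())
                     if h.e_value < secondary_evalue]
            hits5 = sorted(hits5, key=lambda h: (-h.bit_score, h.e_value,
                                                 h.subject_id))[:5]
            labels = set()
            for h in hits5:
                c = synonyms.canonical(label_of(h))
                labels.add(c)
                cum_bits[c] = cum_bits.get(c, 0.0) + h.bit_score
            per_list.append(labels)
        common = set.intersection(*per_list) if per_list else set()
        matching = sorted(common & set(canon))
        if len(matching) == 1:
            return AnnotationAssignment(group.id, matching[0], "resolved_top5",
                                        evidence)
        if len(matching) > 1:
            winner = max(matching, key=lambda c: (cum_bits.get(c, 0.0), c))
            return AnnotationAssignment(group.id, winner, "resolved_top5", evidence)

    return AnnotationAssignment(group.id, None, "unresolved", evidence)


def annotation_census(assignments: Sequence[AnnotationAssignment]) -> dict:
    """Counts by status, plus gene-label multiplicity accounting.

    Unresolved-multiple isogroups count as annotated (they had hits), but
    carry no label and are excluded from the label multiplicity statistics.
    """
    by_status: dict[str, int] = {}
    for a in assignments:
        by_status[a.status] = by_status.get(a.status, 0) + 1
    labeled = [a.gene_label for a in assignments if a.gene_label is not None]
    counts = pd.Series(labeled).value_counts() if labeled else pd.Series(dtype=int)
    multi = counts[counts > 1]
    return {
        "by_status": by_status,
        "n_annotated": sum(n for s, n in by_status.items() if s != "none"),
        "n_labeled": len(labeled),
        "n_unique_labels": int(counts.size),
        "n_labels_single_isogroup": int((counts == 1).sum()),
        "n_labels_multi_isogroup": int(multi.size),
        "n_isogroups_on_multi_labels": int(multi.sum()),
        "mean_isogroups_per_multi_label": float(multi.mean()) if multi.size else 0.0,
    }


class LookupTable:
    """subject_id -> list of terms (GO ids, pathway ids, orthology groups)."""

    def __init__(self, mapping: Mapping[str, Sequence[str]]):
        self._map = {k: list(v) for k, v in mapping.items()}

    def get(self, subject_id: str) -> list[str] | None:
        return self._map.get(subject_id)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LookupTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["subject_id", "term"],
                         dtype=str)
        m: dict[str, list[str]] = {}
        for r in df.itertuples(index=False):
            m.setdefault(r.subject_id, []).append(r.term)
        return cls(m)


def join_terms(top_hits: Mapping[str, AlignmentHit],
               table: LookupTable,
               evalue_cutoff: float,
               unit_of: Mapping[str, str] | None = None
               ) -> tuple[dict[str, list[str]], set[str]]:
    """Assign lookup-table terms to units via their top subjects.

    ``unit_of`` maps isotig -> isogroup; queries absent from it are their
    own unit (singletons).  An isogroup whose isotigs pass the cutoff with
    different subjects is flagged multi-annotation and excluded (returned in
    the second element).  Subjects missing from the table are skipped with a
    warning.
    """
    unit_subjects: dict[str, set[str]] = {}
    for q, h in top_hits.items():
        if h.e_value >= evalue_cutoff:
            continue
        unit = unit_of.get(q, q) if unit_of is not None else q
        unit_subjects.setdefault(unit, set()).add(h.subject_id)

    terms: dict[str, list[str]] = {}
    excluded: set[str] = set()
    for unit, subjects in sorted(unit_subjects.items()):
        if len(subjects) > 1:
            excluded.add(unit)
            continue
        (subject,) = subjects
        t = table.get(subject)
        if t is None:
            log.warning("join_terms: subject %s for unit %s not in lookup table; "
                        "unit skipped", subject, unit)
            continue
        terms[unit] = list(t)
    return terms, excluded
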