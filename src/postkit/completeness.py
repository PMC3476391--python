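"""Core-gene completeness by reciprocal best alignment.

A transcriptome is scored against a panel of conserved single-copy genes
(e.g. the 716 universal bilaterian KOG set): a core gene counts as
recovered iff some transcript and that gene are each other's best-scoring
alignment in opposite-direction protein searches.  Recovery percentage,
mean identity, and mean fraction of the core protein covered are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import top_hit
from .io import AlignmentHit

log = logging.getLogger("postkit")


@dataclass
class CoreGeneSet:
    lengths: dict[str, int]  # gene id -> protein length (aa)

    def __post_init__(self) -> None:
        for g, n in self.lengths.items():
            if n < 1:
                raise ValueError(f"core gene {g}: length must be >= 1")

    def __len__(self) -> int:
        return len(self.lengths)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoreGeneSet":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"],
                         dtype={"gene_id": str, "length": int})
        if df["gene_id"].duplicated().any():
            raise ValueError(f"{path}: duplicate core gene ids")
        return cls(dict(zip(df["gene_id"], df["length"])))


@dataclass
class RecoveryReport:
    n_core: int
    n_recovered: int
    percent_recovered: float
    mean_identity: float
    mean_covered_fraction: float
    mean_covered_aa: float


def reciprocal_best_hits(forward: Iterable[AlignmentHit],
                         reverse: Iterable[AlignmentHit],
                         evalue_cutoff: float) -> set[tuple[str, str]]:
    """Pairs (transcript, core gene) that are mutual best passing hits.

    'Best' = highest bit score, ties broken by lower e-value then
    lexicographic subject id; the e-value cutoff is a strict inequality.
    Row order of the input tables is irrelevant.
    """
    fwd_best = top_hit(forward, evalue_cutoff)   # transcript -> best core hit
    rev_best = top_hit(reverse, evalue_cutoff)   # core gene  -> best transcript hit
    pairs = set()
    for q, h in fwd_best.items():
        g = h.subject_id
        back = rev_best.get(g)
        if back is not None and back.subject_id == q:
            pairs.add((q, g))
    return pairs


def recovery_report(pairs: set[tuple[str, str]],
                    core: CoreGeneSet,
                    forward: Iterable[AlignmentHit]) -> RecoveryReport:
    """Recovery statistics over the reciprocal-best pairs.

    For each recovered core gene the single best-bit forward alignment is
    used; covered fraction = aligned span on the core protein / protein
    length.  An empty pair set reports zeros with a warning.
    """
    if not pairs:
        log.warning("recovery_report: no reciprocal best pairs; reporting zeros")
        return RecoveryReport(len(core), 0, 0.0, 0.0, 0.0, 0.0)

    pair_set = set(pairs)
    best: dict[tuple[str, str], AlignmentHit] = {}
    for h in forward:
        key = (h.query_id, h.subject_id)
        if key not in pair_set:
            continue
        cur = best.get(key)
        if cur is None or (h.bit_score, -h.e_value) > (cur.bit_score, -cur.e_value):
            best[key] = h

    idents, fracs, spans = [], [], []
    for (q, g), h in best.items():
        length = core.lengths.get(g)
        if length is None:
            log.warning("recovery_report: core gene %s missing from gene set; skipped", g)
            continue
        span = h.s_end - h.s_start + 1
        idents.append(h.percent_identity)
        spans.append(span)
        fracs.append(span / length)

    n_rec = len({g for _, g in pair_set})
    return RecoveryReport(
        n_core=len(core),
        n_recovered=n_rec,
        percent_recovered=100.0 * n_rec / len(core),
        mean_identity=sum(idents) / len(idents) if idents else 0.0,
        mean_covered_fraction=sum(fracs) / len(fracs) if fracs else 0.0,
        mean_covered_aa=sum(spans) / len(spans) if spans else 0.0,
    )
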