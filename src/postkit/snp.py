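"""EST SNP calling from read-to-isotig alignments.

Cleaned reads aligned back to the assembled transcriptome are filtered
(e < 1e-5, >= 95% identity, at most 5 bp unaligned overhang per read end,
reads touching more than one isogroup dropped), edge-trimmed (the first and
last five read bases never contribute), and piled up per isotig position.
A site is a potential SNP when the minor allele is supported by at least
three reads at a frequency strictly above 20% of the non-gap depth; gap
"alleles" never form calls, since homopolymer indels are the dominant 454
error mode.  Calls repeated across the isotigs of one isogroup (shared
contigs) are collapsed to a single unique representative, and the variant
rate per kb and the binomial expected-false-call bound are reported.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .config import PipelineConfig

log = logging.getLogger("postkit")

BASES = ("A", "C", "G", "T")
GAP = "-"


@dataclass
class ReadAlignment:
    """A gapped pairwise alignment of a read against an isotig.

    Coordinates are 0-based half-open.  ``read_aln`` and ``isotig_aln`` are
    equal-length strings with '-' for gaps, in isotig orientation; for
    ``strand`` '-' the read was reverse-complemented into isotig
    orientation, and read coordinates still refer to the original read.
    """
    read_id: str
    isotig_id: str
    read_start: int
    read_end: int
    isotig_start: int
    isotig_end: int
    read_aln: str
    isotig_aln: str
    read_length: int
    percent_identity: float
    e_value: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.read_aln) != len(self.isotig_aln):
            raise ValueError(f"{self.read_id}: aligned strings differ in length")
        n_read = sum(1 for c in self.read_aln if c != GAP)
        if n_read != self.read_end - self.read_start:
            raise ValueError(f"{self.read_id}: read span inconsistent with alignment")


@dataclass
class PileupColumn:
    isotig_id: str
    position: int  # 0-based
    counts: Counter  # over A,C,G,T,'-'

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def nongap_depth(self) -> int:
        return sum(v for b, v in self.counts.items() if b != GAP)


@dataclass
class SnpCall:
    isotig_id: str
    isogroup_id: str | None
    position: int  # 0-based internal
    major: str
    minor: str
    minor_count: int
    depth: int  # non-gap depth
    unique: bool = False

    @property
    def minor_frequency(self) -> float:
        return self.minor_count / self.depth


def filter_alignments(alignments: Iterable[ReadAlignment],
                      group_of: Mapping[str, str],
                      cfg: PipelineConfig | None = None) -> list[ReadAlignment]:
    """Apply the alignment-quality and multi-isogroup filters.

    Keeps alignments with e-value strictly below the cutoff, identity at or
    above the minimum, and unaligned read overhang of at most
    ``snp_edge_slack`` bases at each end; then removes every alignment of
    any read whose retained alignments touch more than one isogroup.
    """
    cfg = cfg or PipelineConfig()
    kept = []
    for a in alignments:
        if a.isotig_id not in group_of:
            raise ValueError(f"isotig {a.isotig_id} missing from isogroup map")
        if a.e_value >= cfg.snp_evalue:
            continue
        if a.percent_identity < cfg.snp_min_identity:
            continue
        if a.read_start > cfg.snp_edge_slack:
            continue
        if a.read_length - a.read_end > cfg.snp_edge_slack:
            continue
        kept.append(a)

    groups_of_read: dict[str, set[str]] = defaultdict(set)
    for a in kept:
        groups_of_read[a.read_id].add(group_of[a.isotig_id])
    multi = {r for r, gs in groups_of_read.items() if len(gs) > 1}
    if multi:
        log.info("filter_alignments: dropping %d reads spanning multiple isogroups",
                 len(multi))
    return [a for a in kept if a.read_id not in multi]


def trim_and_pileup(alignments: Iterable[ReadAlignment],
                    cfg: PipelineConfig | None = None) -> list[PileupColumn]:
    """Tally aligned bases per isotig position, edge-trimming each read.

    Read bases within ``snp_trim`` positions of either end of the original
    read contribute nothing; deletions in the read (gap in ``read_aln``)
    count toward the gap allele of the spanned column; insertions consume
    read bases but no isotig column.
    """
    cfg = cfg or PipelineConfig()
    trim = cfg.snp_trim
    tallies: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for a in alignments:
        ipos = a.isotig_start
        consumed = 0  # read bases consumed so far, in alignment order
        for rb, tb in zip(a.read_aln, a.isotig_aln):
            if rb != GAP:
                # original-read coordinate of this base
                if a.strand == "+":
                    rpos = a.read_start + consumed
                else:
                    rpos = a.read_end - 1 - consumed
                consumed += 1
            else:
                rpos = None
            if tb != GAP:
                if rb == GAP:
                    # deletion: attribute to the neighbouring read position
                    prev = consumed - 1
                    if a.strand == "+":
                        rpos = a.read_start + max(prev, 0)
                    else:
                        rpos = a.read_end - 1 - max(prev, 0)
                if rpos is not None and trim <= rpos <= a.read_length - trim - 1:
                    tallies[(a.isotig_id, ipos)][rb if rb != GAP else GAP] += 1
                ipos += 1
    return [PileupColumn(isotig_id=t, position=p, counts=c)
            for (t, p), c in sorted(tallies.items())]


def call_snps(columns: Iterable[PileupColumn],
              cfg: PipelineConfig | None = None) -> list[SnpCall]:
    """Call biallelic SNPs from pileup columns.

    Major and minor alleles are the two most frequent non-gap bases; a call
    requires minor support of at least ``snp_min_support`` reads and a
    minor frequency strictly above ``snp_min_maf`` of the non-gap depth.
    Gap alleles are ignored entirely; any third allele is not tested.
    """
    cfg = cfg or PipelineConfig()
    calls = []
    for col in columns:
        ranked = sorted(((col.counts.get(b, 0), b) for b in BASES),
                        key=lambda x: (-x[0], x[1]))
        (maj_n, maj), (min_n, mnr) = ranked[0], ranked[1]
        depth = col.nongap_depth
        if maj_n == 0 or min_n < cfg.snp_min_support:
            continue
        if min_n / depth <= cfg.snp_min_maf:
            continue
        calls.append(SnpCall(isotig_id=col.isotig_id, isogroup_id=None,
                             position=col.position, major=maj, minor=mnr,
                             minor_count=min_n, depth=depth))
    return calls


def dedup_calls(calls: Sequence[SnpCall],
                group_of: Mapping[str, str],
                contig_position: Mapping[tuple[str, int], tuple[str, int]] | None = None
                ) -> list[SnpCall]:
    """Flag one unique representative per redundancy class.

    Within an isogroup, calls sharing major allele, minor allele and
    position key are one class: the position key is the underlying contig
    position when a map is supplied, else the isotig-local position (the
    isotigs of an isogroup share leading contigs, so identical local
    positions flag the same underlying site).  The representative is the
    call with the greatest minor-allele support, ties broken by the
    smallest isotig id.  Calls in different isogroups are never merged.
    """
    annotated = []
    for c in calls:
        ig = group_of.get(c.isotig_id)
        if ig is None:
            raise ValueError(f"isotig {c.isotig_id} missing from isogroup map")
        annotated.append(SnpCall(c.isotig_id, ig, c.position, c.major, c.minor,
                                 c.minor_count, c.depth))
    classes: dict[tuple, list[SnpCall]] = defaultdict(list)
    for c in annotated:
        if contig_position is not None:
            key_pos = contig_position.get((c.isotig_id, c.position),
                                          (c.isotig_id, c.position))
        else:
            key_pos = c.position
        classes[(c.isogroup_id, c.major, c.minor, key_pos)].append(c)
    for members in classes.values():
        best = min(members, key=lambda c: (-c.minor_count, c.isotig_id))
        best.unique = True
    return annotated


def variant_rate(n_unique_calls: int, assembled_bases: int) -> float:
    """Unique variants per 1000 bp of assembled sequence."""
    if assembled_bases <= 0:
        raise ValueError("assembled_bases must be > 0")
    return 1000.0 * n_unique_calls / assembled_bases


def expected_false_snps(error_rate: float, depth: int, min_support: int,
                        n_sites: int = 1) -> float:
    """Expected false calls from sequencing error alone.

    n_sites times the exact binomial tail P(X >= min_support | depth,
    error_rate): the chance that independent substitution errors pile up to
    the minimum read support at one site.
    """
    if not (0 <= error_rate <= 1):
        raise ValueError("error_rate must lie in [0, 1]")
    if depth < 1 or min_support < 1 or n_sites < 0:
        raise ValueError("depth, min_support must be >= 1 and n_sites >= 0")
    return float(n_sites * stats.binom.sf(min_support - 1, depth, error_rate))


ALIGNMENT_COLUMNS = [
    "read_id", "isotig_id", "read_start", "read_end", "isotig_start",
    "isotig_end", "read_aln", "isotig_aln", "read_length",
    "percent_identity", "e_value", "strand",
]


def write_alignments_tsv(alignments: Iterable[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
        for a in alignments:
            fh.write("\t".join(str(getattr(a, c)) for c in ALIGNMENT_COLUMNS) + "\n")


def read_alignments_tsv(path) -> list[ReadAlignment]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "isotig_id": str,
                                            "read_aln": str, "isotig_aln": str,
                                            "strand": str})
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing alignment columns {sorted(missing)}")
    return [ReadAlignment(
        read_id=r.read_id, isotig_id=r.isotig_id,
        read_start=int(r.read_start), read_end=int(r.read_end),
        isotig_start=int(r.isotig_start), isotig_end=int(r.isotig_end),
        read_aln=r.read_aln, isotig_aln=r.isotig_aln,
        read_length=int(r.read_length),
        percent_identity=float(r.percent_identity),
        e_value=float(r.e_value), strand=r.strand)
        for r in df.itertuples(index=False)]
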