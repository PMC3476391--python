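"""Readers and writers for the external formats, plus read cleaning.

Formats: FASTA (sequences), 12-column tab-separated alignment hit tables
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore), minimal VCF 4.2 output for variant calls, and TSV for
everything else.  Internal coordinates are 0-based half-open; all file
output is 1-based inclusive to match the BLAST-tabular and VCF conventions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("postkit")

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line/row."""


@dataclass
class SequenceRecord:
    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "align_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
]


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int          # 1-based inclusive
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    strand: str = "+"     # '-' when the raw row had s_start > s_end

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: q_start > q_end")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity outside [0, 100]")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords.

    Sequences are uppercased and U is mapped to T.  Duplicate ids, empty
    sequences, and text before the first header raise :class:`ParseError`
    with the line number.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r} "
                             f"(line {_line_of_header(path, rec.id)})")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=seq, description=rec.description))
    return records


def _validate_fasta_lines(path: Path) -> None:
    with open(path) as fh:
        header_line = None
        body_seen = False
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise ParseError(f"{path}: empty FASTA header at line {i}")
                if header_line is not None and not body_seen:
                    raise ParseError(f"{path}: record at line {header_line} has an "
                                     f"empty sequence")
                header_line, body_seen = i, False
            else:
                if header_line is None:
                    raise ParseError(f"{path}: sequence data before any header "
                                     f"at line {i}")
                body_seen = True
        if header_line is not None and not body_seen:
            raise ParseError(f"{path}: record at line {header_line} has an empty sequence")


def _line_of_header(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0] == rec_id:
                return i
    return -1


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                if desc:
                    header += f" {desc}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column BLAST-tabular hit file, preserving row order.

    Reverse-strand rows (s_start > s_end) are normalized: coordinates are
    swapped and ``strand`` is set to '-'.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                         comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed hit table: {exc}") from exc
    if df.empty:
        return []
    bad = df[df["bit_score"].isna()]
    if len(bad):
        raise ParseError(f"{path}: row {bad.index[0] + 1} has fewer than 12 columns")
    hits = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            s_start, s_end = int(row.s_start), int(row.s_end)
            strand = "+"
            if s_start > s_end:
                s_start, s_end, strand = s_end, s_start, "-"
            hits.append(AlignmentHit(
                query_id=row.query_id, subject_id=row.subject_id,
                percent_identity=float(row.percent_identity),
                align_length=int(row.align_length),
                mismatches=int(row.mismatches), gap_opens=int(row.gap_opens),
                q_start=int(row.q_start), q_end=int(row.q_end),
                s_start=s_start, s_end=s_end,
                e_value=float(row.e_value), bit_score=float(row.bit_score),
                strand=strand))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            s_start, s_end = h.s_start, h.s_end
            if h.strand == "-":
                s_start, s_end = s_end, s_start
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.subject_id, h.percent_identity, h.align_length,
                h.mismatches, h.gap_opens, h.q_start, h.q_end,
                s_start, s_end, h.e_value, h.bit_score)) + "\n")


# ---------------------------------------------------------------------------
# read cleaning

def _trim_poly_tail(seq: str, min_run: int = 8) -> str:
    """Remove a 3' run of >= min_run A's allowing one interruption."""
    m = re.search(r"A+(?:[^A]A+)?$", seq)
    if m and m.group(0).count("A") >= min_run:
        return seq[: m.start()]
    return seq


def _trim_poly_head(seq: str, min_run: int = 8) -> str:
    """Remove a 5' run of >= min_run T's allowing one interruption."""
    m = re.match(r"T+(?:[^T]T+)?", seq)
    if m and m.group(0).count("T") >= min_run:
        return seq[m.end():]
    return seq


def clean_reads(reads: Sequence[SequenceRecord],
                adaptors: Sequence[str] = (),
                min_length: int = 31) -> list[SequenceRecord]:
    """Strip adaptor prefixes/suffixes and terminal polyA/polyT, drop short reads.

    Adaptors are removed by exact match (longest adaptor first); terminal
    polyA (3') / polyT (5') runs of at least 8 bases with at most one
    interruption are removed.  Trimming repeats until a fixed point, so the
    operation is idempotent.  Reads shorter than ``min_length`` after
    trimming are dropped.
    """
    ordered = sorted((a.upper() for a in adaptors), key=len, reverse=True)
    out = []
    for rec in reads:
        seq = rec.seq
        while True:
            before = seq
            for a in ordered:
                if a and seq.startswith(a):
                    seq = seq[len(a):]
                if a and seq.endswith(a):
                    seq = seq[: -len(a)]
            seq = _trim_poly_head(_trim_poly_tail(seq))
            if seq == before:
                break
        if len(seq) >= min_length:
            out.append(SequenceRecord(id=rec.id, seq=seq, description=rec.description))
    return out


# ---------------------------------------------------------------------------
# VCF output for variant calls

VCF_HEADER_META = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Non-gap read depth at site">',
    '##INFO=<ID=MAC,Number=1,Type=Integer,Description="Minor allele read count">',
    '##INFO=<ID=ISOGROUP,Number=1,Type=String,Description="Isogroup of the isotig">',
    '##INFO=<ID=UNIQUE,Number=0,Type=Flag,Description="Call is the unique representative of its redundancy class">',
]


def write_vcf(calls, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write variant calls as minimal VCF 4.2 (CHROM = isotig id, POS 1-based)."""
    calls = list(calls)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=postkit\n")
        contigs: dict[str, int] = dict(contig_lengths or {})
        for c in calls:
            contigs.setdefault(c.isotig_id, 0)
        for cid, length in contigs.items():
            if length:
                fh.write(f"##contig=<ID={cid},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={cid}>\n")
        for line in VCF_HEADER_META:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.isotig_id, c.position)):
            info = f"DP={c.depth};MAC={c.minor_count};ISOGROUP={c.isogroup_id}"
            if c.unique:
                info += ";UNIQUE"
            fh.write(f"{c.isotig_id}\t{c.position + 1}\t.\t{c.major}\t{c.minor}"
                     f"\t.\tPASS\t{info}\n")


def read_vcf(path: str | Path):
    """Read back a postkit VCF via pysam; returns a list of SnpCall records."""
    import pysam

    from .snp import SnpCall

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            depth = int(info["DP"])
            mac = int(info["MAC"])
            calls.append(SnpCall(
                isotig_id=rec.chrom, isogroup_id=str(info["ISOGROUP"]),
                position=rec.pos - 1, major=rec.ref, minor=rec.alts[0],
                minor_count=mac, depth=depth,
                unique=bool(info.get("UNIQUE", False))))
    return calls
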