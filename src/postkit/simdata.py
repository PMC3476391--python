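"""Synthetic inputs with known truth for every pipeline stage.

The generators emulate the structure of a normalized-library 454
transcriptome study: genes with alternative isoforms sharing flanking
exon-contigs (so the assembler graph is a diamond), two diploid
individuals carrying planted biallelic SNPs at controlled minor-allele
frequency, pyrosequencing-like reads (log-normal lengths around a 372 bp
mean, substitutions at 0.022%, optional homopolymer indels), hit tables
against a mock proteome with synonym noise and a core-gene panel with
reciprocal-best structure, and per-individual probe intensities with a
random-probe null compartment.  Every generator is deterministic under its
seed, and its outputs are valid inputs to the downstream modules with no
manual edits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import LookupTable, SynonymMap
from .completeness import CoreGeneSet
from .io import AlignmentHit, SequenceRecord
from .snp import ReadAlignment

BASES = np.array(list("ACGT"))


@dataclass
class PlantedSnp:
    isotig_id: str
    position: int  # 0-based on the transcript
    ref: str
    alt: str
    maf: float


@dataclass
class SimTruth:
    rng_seed: int
    # gene id -> list of isoform contig chains (tuples of contig ids)
    isoforms: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    contig_seqs: dict[str, str] = field(default_factory=dict)
    snps: list[PlantedSnp] = field(default_factory=list)
    # unit id -> set of (tissue, sex) groups in which it is truly expressed
    expressed: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    core_present: set[str] = field(default_factory=set)

    @property
    def expected_isogroups(self) -> list[frozenset[str]]:
        return [frozenset(c for chain in chains for c in chain)
                for chains in self.isoforms.values()]

    def transcript_ids(self) -> list[str]:
        return [f"{g}_t{j}" for g, chains in self.isoforms.items()
                for j in range(1, len(chains) + 1)]

    def transcript_seq(self, tid: str) -> str:
        gene, j = tid.rsplit("_t", 1)
        chain = self.isoforms[gene][int(j) - 1]
        return "".join(self.contig_seqs[c] for c in chain)

    def transcript_group(self) -> dict[str, str]:
        return {f"{g}_t{j}": g for g, chains in self.isoforms.items()
                for j in range(1, len(chains) + 1)}

    def to_json(self, path: str | Path) -> None:
        obj = {
            "rng_seed": self.rng_seed,
            "isoforms": {g: [list(c) for c in chains]
                         for g, chains in self.isoforms.items()},
            "snps": [vars(s) for s in self.snps],
            "expressed": {u: sorted(map(list, gs))
                          for u, gs in self.expressed.items()},
            "core_present": sorted(self.core_present),
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def simulate_transcriptome(n_genes: int = 30,
                           isoform_probs: Sequence[float] = (0.81, 0.14, 0.05),
                           contig_length_mean: float = 884.0,
                           contig_length_cv: float = 0.6,
                           min_contig_length: int = 150,
                           rng_seed: int = 0
                           ) -> tuple[list, list, SimTruth]:
    """Generate gene models with shared-flank alternative isoforms.

    A k-isoform gene (k drawn from ``isoform_probs`` for k = 1, 2, 3)
    becomes a first contig, k alternative middle contigs and a last contig;
    each isoform chain is first-alt_i-last, and every junction is supported
    by oriented broken-read links.  Single-isoform genes are one unlinked
    contig.  Returns (contigs, links, truth) using the isogrouping module's
    Contig/BrokenReadLink types.
    """
    from .isogroup import BrokenReadLink, Contig

    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    probs = np.asarray(isoform_probs, dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(rng_seed)
    sigma = float(np.sqrt(np.log1p(contig_length_cv ** 2)))
    mu = float(np.log(contig_length_mean) - sigma ** 2 / 2)

    def draw_len() -> int:
        return max(min_contig_length, int(rng.lognormal(mu, sigma)))

    truth = SimTruth(rng_seed=rng_seed)
    contigs, links = [], []
    link_no = 0
    for i in range(1, n_genes + 1):
        gene = f"g{i:04d}"
        k = int(rng.choice(len(probs), p=probs)) + 1
        if k == 1:
            cid = f"{gene}c1"
            seq = _random_seq(rng, draw_len())
            contigs.append(Contig(id=cid, length=len(seq), depth=12.0, seq=seq))
            truth.contig_seqs[cid] = seq
            truth.isoforms[gene] = [(cid,)]
            continue
        ids = [f"{gene}c{j}" for j in range(1, k + 3)]  # first, alts..., last
        first, last = ids[0], ids[-1]
        alts = ids[1:-1]
        for cid in ids:
            seq = _random_seq(rng, draw_len())
            contigs.append(Contig(id=cid, length=len(seq), depth=12.0, seq=seq))
            truth.contig_seqs[cid] = seq
        truth.isoforms[gene] = [(first, a, last) for a in alts]
        for a in alts:
            for pair in ((first, a), (a, last)):
                link_no += 1
                links.append(BrokenReadLink(read_id=f"lnk{link_no:06d}",
                                            contig_a=pair[0], contig_b=pair[1],
                                            orientation="forward"))
    return contigs, links, truth


def simulate_reads(truth: SimTruth,
                   mean_length: float = 372.0,
                   length_cv: float = 0.3,
                   error_rate: float = 2.2e-4,
                   indel_hp_rate: float = 0.0,
                   depth: float = 12.0,
                   snps_per_transcript: float = 1.0,
                   maf_range: tuple[float, float] = (0.25, 0.5),
                   rng_seed: int = 0
                   ) -> tuple[list[SequenceRecord], list[ReadAlignment]]:
    """Sample pyrosequencing-like reads from the truth transcripts.

    Biallelic SNPs are planted on each transcript (Poisson with mean
    ``snps_per_transcript``, interior positions only) and recorded in
    ``truth.snps``; each read draws the minor allele with probability MAF,
    then substitution errors at ``error_rate`` and, for homopolymer runs of
    length >= 3, +-1 bp indels at ``indel_hp_rate`` per run base.  Reads
    carry their true gapped alignment so the SNP caller runs without an
    external aligner.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(rng_seed)
    sigma = float(np.sqrt(np.log1p(length_cv ** 2)))
    mu = float(np.log(mean_length) - sigma ** 2 / 2)
    truth.snps = []
    reads: list[SequenceRecord] = []
    alignments: list[ReadAlignment] = []
    read_no = 0

    for tid in truth.transcript_ids():
        tseq = truth.transcript_seq(tid)
        n = len(tseq)
        snp_sites: dict[int, PlantedSnp] = {}
        n_snps = rng.poisson(snps_per_transcript)
        margin = 15
        if n - 2 * margin > n_snps > 0:
            for pos in sorted(rng.choice(np.arange(margin, n - margin),
                                         size=n_snps, replace=False)):
                pos = int(pos)
                ref = tseq[pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                snp = PlantedSnp(isotig_id=tid, position=pos, ref=ref, alt=alt,
                                 maf=float(rng.uniform(*maf_range)))
                snp_sites[pos] = snp
                truth.snps.append(snp)

        n_reads = max(1, int(round(depth * n / mean_length)))
        for _ in range(n_reads):
            length = int(np.clip(rng.lognormal(mu, sigma), 40, n))
            start = int(rng.integers(0, n - length + 1))
            ref_piece = tseq[start:start + length]
            read_chars = list(ref_piece)
            for off in range(length):
                site = snp_sites.get(start + off)
                if site is not None and rng.random() < site.maf:
                    read_chars[off] = site.alt
                if rng.random() < error_rate:
                    read_chars[off] = str(rng.choice(
                        [b for b in "ACGT" if b != read_chars[off]]))
            read_aln = read_chars[:]
            isotig_aln = list(ref_piece)
            if indel_hp_rate > 0:
                read_aln, isotig_aln = _apply_hp_indels(
                    read_aln, isotig_aln, rng, indel_hp_rate)
            read_seq = "".join(c for c in read_aln if c != "-")
            if len(read_seq) < 40:
                continue
            read_no += 1
            rid = f"read{read_no:07d}"
            matches = sum(1 for a, b in zip(read_aln, isotig_aln) if a == b)
            reads.append(SequenceRecord(id=rid, seq=read_seq))
            alignments.append(ReadAlignment(
                read_id=rid, isotig_id=tid,
                read_start=0, read_end=len(read_seq),
                isotig_start=start,
                isotig_end=start + sum(1 for c in isotig_aln if c != "-"),
                read_aln="".join(read_aln), isotig_aln="".join(isotig_aln),
                read_length=len(read_seq),
                percent_identity=100.0 * matches / len(read_aln),
                e_value=1e-60, strand="+"))
    return reads, alignments


def _apply_hp_indels(read_aln: list[str], isotig_aln: list[str],
                     rng: np.random.Generator, rate: float
                     ) -> tuple[list[str], list[str]]:
    """+-1 bp length changes of homopolymer runs (the dominant 454 error)."""
    out_r, out_t = [], []
    i = 0
    n = len(read_aln)
    while i < n:
        j = i
        while j < n and isotig_aln[j] == isotig_aln[i]:
            j += 1
        run = j - i
        out_r.extend(read_aln[i:j])
        out_t.extend(isotig_aln[i:j])
        if run >= 3 and rng.random() < rate * run:
            if rng.random() < 0.5:
                out_r.append(isotig_aln[i])   # insertion in the read
                out_t.append("-")
            else:
                out_r[-1] = "-"               # deletion from the read
        i = j
    return out_r, out_t


def simulate_hits(truth: SimTruth,
                  synonym_noise: float = 0.1,
                  n_core: int = 100,
                  core_fraction_present: float = 0.9,
                  rng_seed: int = 0) -> dict:
    """Hit tables, synonym map, core-gene panel and term lookup tables.

    Every transcript's top hit is its gene's true protein (a synonymous
    alternative accession for a ``synonym_noise`` fraction), with a weaker
    decoy hit below it.  A ``core_fraction_present`` share of the core
    genes is planted with mutual-best reciprocal structure on host
    transcripts; the remainder get no hits.  Returns a dict with keys
    forward, reverse, core_forward, core_reverse, synonyms, subject_labels,
    core, go, kegg, ortho.
    """
    if not (0 <= synonym_noise <= 1 and 0 <= core_fraction_present <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    genes = sorted(truth.isoforms)
    tids = truth.transcript_ids()
    group_of = truth.transcript_group()

    subject_labels: dict[str, str] = {}
    synonyms = SynonymMap()
    forward: list[AlignmentHit] = []
    go, kegg, ortho = {}, {}, {}

    def hit(q, s, bit, e, slen=400, ident=85.0):
        span = max(30, int(slen * 0.6))
        return AlignmentHit(query_id=q, subject_id=s, percent_identity=ident,
                            align_length=span, mismatches=int(span * 0.15),
                            gap_opens=1, q_start=1, q_end=span * 3,
                            s_start=1, s_end=span, e_value=e, bit_score=bit)

    for gi, gene in enumerate(genes, start=1):
        subj, alt_subj = f"P{gi:04d}", f"P{gi:04d}alt"
        label = f"GENE{gi}"
        subject_labels[subj] = label
        subject_labels[alt_subj] = f"gene{gi} isoform x"
        synonyms.add(subject_labels[alt_subj], label)
        go[subj] = [f"GO:{7000000 + gi:07d}"]
        kegg[subj] = [f"ko{10000 + gi:05d}"]
        ortho[subj] = [f"EOG{gi:05d}"]
        for s2 in (alt_subj,):
            go[s2], kegg[s2], ortho[s2] = go[subj], kegg[subj], ortho[subj]
        for j in range(1, len(truth.isoforms[gene]) + 1):
            tid = f"{gene}_t{j}"
            use_alt = rng.random() < synonym_noise
            top = alt_subj if use_alt else subj
            forward.append(hit(tid, top, bit=250 + float(rng.normal(0, 5)), e=1e-60))
            decoy = f"P{(gi % len(genes)) + 1:04d}"
            if decoy not in (top,):
                forward.append(hit(tid, decoy, bit=80 + float(rng.normal(0, 3)),
                                   e=1e-8))

    # core-gene panel with reciprocal-best structure
    core_ids = [f"KOG{j:04d}" for j in range(1, n_core + 1)]
    core_len = {g: int(rng.integers(200, 800)) for g in core_ids}
    n_present = int(round(core_fraction_present * n_core))
    if n_present > len(tids):
        raise ValueError(
            f"cannot plant {n_present} core homologs on {len(tids)} transcripts; "
            f"each reciprocal-best pair needs a distinct host — "
            f"generate more genes or lower n_core/core_fraction_present")
    present = set(rng.choice(core_ids, size=n_present, replace=False).tolist())
    truth.core_present = present
    core_forward: list[AlignmentHit] = []
    core_reverse: list[AlignmentHit] = []
    for j, g in enumerate(sorted(present)):
        host = tids[j]
        other = tids[(j + 1) % len(tids)]
        slen = core_len[g]
        span = int(slen * float(rng.uniform(0.5, 0.9)))
        ident = float(rng.uniform(75, 95))
        h = AlignmentHit(query_id=host, subject_id=g, percent_identity=ident,
                         align_length=span, mismatches=int(span * 0.1),
                         gap_opens=0, q_start=1, q_end=span * 3,
                         s_start=1, s_end=span, e_value=1e-40,
                         bit_score=300 + float(rng.normal(0, 5)))
        core_forward.append(h)
        if other != host:
            core_forward.append(hit(other, g, bit=90.0, e=1e-7, slen=slen))
        core_reverse.append(hit(g, host, bit=300.0, e=1e-40, slen=slen))

    return {
        "forward": forward,
        "reverse": [],  # transcripts are the only queries of the mock proteome
        "core_forward": core_forward,
        "core_reverse": core_reverse,
        "synonyms": synonyms,
        "subject_labels": subject_labels,
        "core": CoreGeneSet(core_len),
        "go": LookupTable(go),
        "kegg": LookupTable(kegg),
        "ortho": LookupTable(ortho),
        "group_of": group_of,
    }


def simulate_expression(truth: SimTruth,
                        n_random: int = 2604,
                        tissues: Sequence[str] = ("liver", "muscle"),
                        sexes: Sequence[str] = ("M", "F"),
                        n_replicates: int = 6,
                        probes_per_unit: int = 3,
                        background_mean: float = 8.0,
                        background_sd: float = 1.0,
                        effect_sd: float = 3.0,
                        expressed_fraction: float = 0.7,
                        rng_seed: int = 0
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Probe manifest, normalized-score matrix and group design with truth.

    Null probes and unexpressed units draw iid Normal(background) scores;
    an ``expressed_fraction`` share of units is shifted upward by
    ``effect_sd`` background standard deviations in one or more randomly
    chosen tissue-sex groups.  True expression is recorded in
    ``truth.expressed``.  Returns (manifest, matrix, design).
    """
    rng = np.random.default_rng(rng_seed)
    units = sorted(truth.contig_seqs) or sorted(truth.isoforms)
    groups = [(t, s) for t in tissues for s in sexes]
    design_rows = [(f"{s}_{t}_{r}", t, s)
                   for t, s in groups for r in range(1, n_replicates + 1)]
    design = pd.DataFrame(design_rows, columns=["individual", "tissue", "sex"])

    rows = [(f"{u}_p{k}", u, "contig")
            for u in units for k in range(1, probes_per_unit + 1)]
    rows += [(f"rnd{k:05d}", None, "random") for k in range(1, n_random + 1)]
    manifest = pd.DataFrame(rows, columns=["probe_id", "target_id", "probe_class"])

    inds = design["individual"].tolist()
    scores = rng.normal(background_mean, background_sd,
                        size=(len(manifest), len(inds)))
    matrix = pd.DataFrame(scores, index=manifest["probe_id"].tolist(), columns=inds)

    truth.expressed = {}
    ind_of_group = {g: design.loc[(design["tissue"] == g[0]) &
                                  (design["sex"] == g[1]), "individual"].tolist()
                    for g in groups}
    for u in units:
        if rng.random() >= expressed_fraction:
            truth.expressed[u] = set()
            continue
        n_g = int(rng.integers(1, len(groups) + 1))
        chosen = [groups[i] for i in
                  sorted(rng.choice(len(groups), size=n_g, replace=False))]
        truth.expressed[u] = set(chosen)
        probe_ids = [f"{u}_p{k}" for k in range(1, probes_per_unit + 1)]
        for g in chosen:
            matrix.loc[probe_ids, ind_of_group[g]] += effect_sd * background_sd
    return manifest, matrix, design


def simulate_pileup_columns(n_sites: int,
                            depth: int = 20,
                            maf_range: tuple[float, float] = (0.3, 0.5),
                            error_rate: float = 2.2e-4,
                            monomorphic_fraction: float = 0.0,
                            rng_seed: int = 0):
    """Pileup columns with planted site-level truth.

    Polymorphic sites carry exactly ``round(maf * depth)`` minor-allele
    reads (the site's true allele balance); a ``monomorphic_fraction``
    share of sites is reference-only.  Every read base is then corrupted
    to a random other base with probability ``error_rate``, so false calls
    on monomorphic sites follow the binomial error model.  Returns
    (columns, truth) where truth maps position -> (major, minor, maf) for
    the polymorphic sites, using the snp module's PileupColumn type.
    """
    from collections import Counter

    from .snp import PileupColumn

    if n_sites < 1 or depth < 1:
        raise ValueError("n_sites and depth must be >= 1")
    rng = np.random.default_rng(rng_seed)
    columns, truth = [], {}
    bases = "ACGT"
    for pos in range(n_sites):
        major = bases[rng.integers(4)]
        is_mono = rng.random() < monomorphic_fraction
        if is_mono:
            pile = [major] * depth
        else:
            minor = bases[(bases.index(major) + 1 + int(rng.integers(3))) % 4]
            maf = float(rng.uniform(*maf_range))
            k = int(round(maf * depth))
            pile = [minor] * k + [major] * (depth - k)
            truth[pos] = (major, minor, maf)
        pile = [str(rng.choice([b for b in bases if b != c]))
                if rng.random() < error_rate else c for c in pile]
        columns.append(PileupColumn(isotig_id="sim", position=pos,
                                    counts=Counter(pile)))
    return columns, truth
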