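# Methods

This note documents the models and procedures `postkit` implements, the
defaults and why they hold, the numerical choices made where a published
protocol is silent, and what the synthetic-data generators do and do not
emulate.

## Isogroup clustering and isotig enumeration

A 454 *de novo* assembler splits a transcript into several contigs wherever
coverage is ambiguous — alternative splice forms, divergent alleles, or
recent duplicates — and records the reads whose alignments were broken
across a boundary. `postkit` treats contigs as nodes and broken-read links
as edges. **Isogroups** are the connected components of this graph (links
undirected for clustering; unlinked contigs are singleton isogroups).
**Isotigs** are the maximal simple paths in which every consecutive contig
pair shares at least one broken read.

Choices where the assembler's internal bookkeeping is not public:

- *Orientation.* When every link carries an orientation, enumeration runs
  on the directed graph (`forward` = contig A precedes contig B). Without
  orientations the graph is undirected and each path is canonicalized by
  its lexicographically smaller endpoint, so output does not depend on
  traversal order. Note the two readings genuinely differ: an undirected
  diamond admits maximal paths (such as alt₁–first–alt₂–last) that the
  directed reading excludes.
- *Support is pairwise.* A path is supported when each consecutive pair is
  linked; no single read is required to phase three or more contigs,
  because the input links are pairwise.
- *Cycles.* Isotigs are simple paths only, so cycles terminate paths and
  are logged. Enumeration stops with a truncation flag at `max_isotigs`
  (default 100 per isogroup), a combinatorial safety valve.

Both algorithms are checked against brute-force oracles (set-merging
components; exhaustive path enumeration with a maximality filter) on random
graphs of up to ten contigs.

## Annotation consolidation

Units (isotigs, singletons) get the label of their best protein hit —
highest bit score among hits with e-value strictly below 10⁻⁵; ties break
by lower e-value, then lexicographic subject id. Isotigs of one isogroup
are splice forms of one gene, so their labels are reduced to one
annotation in four rungs: exact agreement (`single`); one shared canonical
label under a user-supplied synonym table (`collapsed_synonym`) — the
table replaces what was historically manual curation; a gene present in
every isotig's top-five secondary hits (filtered at e < 10⁻¹⁰) and
matching an original label (`resolved_top5`, several candidates resolved
by highest cumulative bit score); else `unresolved` with a null label.
Labels are normalized before any comparison: casefold, strip punctuation
and the noise tokens "predicted", "hypothetical", "-like". Unresolved
isogroups still count as *annotated* in the census (they had significant
hits) but carry no label and drop out of label-level statistics.

Term joins (GO, pathway, orthology group) are lookup-table joins on the
top subject per unit under per-source cutoffs (10⁻¹⁵, 10⁻⁵, 10⁻¹⁰, all
strict `<`). An isogroup whose isotigs pass with different subjects is
flagged multi-annotation and excluded rather than guessed.

## Core-gene completeness

Completeness is measured against a panel of genes known to be single-copy
across bilaterians: a core gene is recovered iff a transcript and that
gene are mutual best hits in opposite-direction protein searches at
e < 10⁻⁵ (tie-break as above; the protocol's own tie-break is unstated).
Coverage is the aligned span on the *core protein* divided by its length,
from the single best-bit forward alignment per recovered gene. Open
reading frame prediction is upstream and out of scope — the module
consumes protein-space hit tables.

## Expression calling

Normalization (limma-style within/between-array) is upstream; the module
consumes one normalized score per probe per individual. The null model is
empirical: per individual, the threshold is the 97.5% quantile of that
individual's random-probe scores, so a single exceedance is significant at
p = 0.025 by construction. The per-unit statistic is the median probe
score (mean of two when a unit has two probes; the single value for
singletons), compared with strict `>`. A unit is called in a tissue–sex
group iff at least 3 of the 6 individuals are called, which drives the
null rate down to the exact binomial tail
P(X ≥ 3 | 6, 0.025) = 2.953 × 10⁻⁴. The historically quoted figure for
this quantity, 0.0006, exceeds the exact tail; `postkit` reports the exact
value and treats 0.0006 only as an upper bound.

Quantile estimator: linear interpolation between order statistics (R's
type 7), documented because the estimator choice moves the threshold by
O(1/n) and the protocol does not specify one. A warning fires below 40
random probes, where the 97.5% quantile becomes unstable.

Probe design allocates up to three non-overlapping 60-mers per contig,
evenly spaced (`k = min(3, ⌊length/60⌋)`, so 130 bp → 2 probes, 59 bp →
skipped), sliding windows off runs of N; one probe per singleton. Random
probes are sampled from an order-k Markov chain (k ∈ {0, 1, 2}, default 1)
fitted to the supplied sequence composition.

## SNP calling

Filters, in order: alignment e < 10⁻⁵; identity ≥ 95%; at most 5 bp of
unaligned read at each end; every alignment of a read discarded when its
retained alignments touch more than one isogroup. The first and last five
bases of each read (original read coordinates — for minus-strand
alignments the trim follows the read's own ends) contribute nothing to the
pileup. A column is a potential SNP when the second most frequent non-gap
base has ≥ 3 reads and a frequency strictly above 20% of the non-gap
depth. Gap alleles are tallied but never called, and are excluded from the
frequency denominator: indels are the dominant 454 error mode and mostly
frameshift artifacts in cDNA. Only the top two alleles are tested.

Deduplication: isotigs of an isogroup share contigs, so one underlying
polymorphism can be called in many isotigs at the same position. Calls in
one isogroup sharing (major, minor, position key) form a redundancy class;
the key is the underlying contig position when an isotig→contig offset map
is supplied, else the isotig-local position. One call per class is flagged
unique: the one with the greatest minor-allele support (reading the
protocol's "isogroup with the greatest number" as the *isotig* with
greatest support — the printed sentence appears to be a typo), ties to the
smallest isotig id.

Reported alongside: unique variants per 1000 assembled bases, and the
expected number of false calls from sequencing error alone,
`n_sites × P(X ≥ min_support | depth, error_rate)` as an exact binomial
tail. At the GS-FLX substitution rate (2.2 × 10⁻⁴) with depth 8 and
support 3 the per-site tail is 5.96 × 10⁻¹⁰; the historically quoted
per-site figure of 1.055 × 10⁻⁸ is not reproducible from these parameters
by a direct binomial, so the module computes the exact tail and accepts an
arbitrary per-site probability where a user wants to reproduce a published
product.

## Synthetic data: what it emulates, and what it does not

`simdata` exists so every module can be exercised end-to-end against known
truth. Defaults mirror the study conditions: contig lengths log-normal
with mean 884 bp; ~19% of genes multi-isoform (probabilities 0.81 / 0.14 /
0.05 for 1 / 2 / 3 isoforms); read lengths log-normal with mean 372 bp and
CV 0.3 (only the mean is published; the CV is a realistic choice for
Titanium reads); substitution rate 2.2 × 10⁻⁴; homopolymer runs of length
L ≥ 3 gain or lose one base with probability `indel_hp_rate · L` (a
minimal parametric form of the dominant 454 error mode, off by default);
planted SNP MAFs uniform on [0.25, 0.5]; 2,604 random probes by default;
6 individuals per tissue–sex group. Multi-isoform genes are always
"diamonds" (shared first and last contig, alternative middles), which is
the canonical skipped/alternative-exon fragmentation pattern.

Simulated reads carry their true gapped alignments, so the SNP caller runs
without an external aligner — alignment error is deliberately absent.
Other simplifications: all reads are plus-strand; every transcript is
sequenced at the same target depth (no expression-level bias, as in a
normalized library); hit tables have a single dominant true subject per
transcript plus weak decoys; probe intensities are iid Gaussian around a
common background with additive shifts for expressed units (no
probe-affinity or dye structure — the calling rule operates on normalized
scores, where those effects are assumed removed). Passing tests therefore
demonstrate the correctness of the *rules* under their stated assumptions,
not robustness to misalignment, cross-hybridization, or normalization
failure.

Two generator notes. `simulate_hits` requires a distinct host transcript
per planted core gene (reciprocal-best pairs are injective by definition),
and raises otherwise rather than silently breaking truth.
`simulate_pileup_columns` plants *site-level* truth — exactly
`round(maf · depth)` minor reads per polymorphic site, plus substitution
errors — and is the generator used for caller sensitivity checks: with
binomial read sampling, a site at MAF 0.3 covered by 10 reads fails the
three-read filter ~38% of the time through sampling alone, which is a
property of finite coverage, not of the caller under test.

## Problem sizes in the checked suites

Oracle equivalence runs on random graphs of ≤ 10 contigs; null calibration
of the expression caller uses 100,000 single-probe units and 20,000 random
probes per individual; planted-SNP sensitivity uses 1,000 sites at depth
12 and the false-call bound 100,000 monomorphic sites at depth 8; the
end-to-end CLI test simulates 8 genes. These sizes keep the full suite
under ten seconds while leaving every statistical assertion's sampling
error well inside its tolerance.

## Conventions and degenerate inputs

Internal coordinates are 0-based half-open; all file output (hit tables,
VCF) is 1-based inclusive. Reverse-strand hit rows are normalized by
swapping subject coordinates and flagging the strand. Every e-value cutoff
is a strict inequality. Empty inputs return empty outputs or zero-filled
reports with a warning, never exceptions; malformed files raise parse
errors naming the offending line or row. The read cleaner (exact adaptor
prefix/suffix removal, terminal polyA/polyT runs of ≥ 8 bases with at most
one interruption, drop reads ≤ 30 bp) iterates to a fixed point so it is
idempotent; the original in-house cleaning tool's exact rules are
unpublished, and this rule is a documented stand-in.
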