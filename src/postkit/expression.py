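"""Microarray probe design and expression calling against a random-probe null.

Each assembled contig is represented by up to three 60-mer probes (one per
singleton); a compartment of "random" probes — 60-mers drawn from a Markov
model of the genome's nucleotide composition — targets nothing and serves
as an empirical null for hybridization signal.  Per individual, the 97.5%
quantile of the random-probe scores is the expression cutoff, so a single
call is significant at p = 0.025; a unit is called expressed in a
tissue-sex group only when at least three of the six individuals exceed
their own cutoff, shrinking the null rate to the exact binomial tail
P(X >= 3 | n=6, p=0.025).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io import SequenceRecord

log = logging.getLogger("postkit")

PROBE_CLASSES = ("contig", "singleton", "random", "control")


@dataclass
class ExpressionCall:
    unit_id: str
    group: tuple[str, str]  # (tissue, sex)
    n_called: int
    called: bool
    any_group_called: bool = False


def design_probes(contigs: Sequence[SequenceRecord],
                  singletons: Sequence[SequenceRecord] = (),
                  cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Select probes per target: up to 3 non-overlapping, evenly spaced
    60-mers per contig (fewer when the sequence is short), one per singleton.

    Windows containing N are slid to the nearest N-free position when
    possible, otherwise that probe is dropped.  Targets shorter than the
    probe length are skipped with a warning.  Returns a manifest DataFrame
    with columns probe_id, target_id, probe_class, start, seq.
    """
    cfg = cfg or PipelineConfig()
    L = cfg.probe_length
    rows = []

    def pick(rec: SequenceRecord, k_max: int, probe_class: str) -> None:
        n = len(rec.seq)
        if n < L:
            log.warning("design_probes: %s shorter than probe length; skipped", rec.id)
            return
        k = min(k_max, n // L)
        starts = ([(n - L) // 2] if k == 1 else
                  [round(i * (n - L) / (k - 1)) for i in range(k)])
        used: list[int] = []
        for s in starts:
            s2 = _slide_n_free(rec.seq, s, L, used)
            if s2 is None:
                log.warning("design_probes: no N-free window for %s near %d", rec.id, s)
                continue
            used.append(s2)
            rows.append((f"{rec.id}_p{len(used)}", rec.id, probe_class, s2,
                         rec.seq[s2:s2 + L]))

    for rec in contigs:
        pick(rec, cfg.probes_per_contig, "contig")
    for rec in singletons:
        pick(rec, 1, "singleton")

    return pd.DataFrame(rows, columns=["probe_id", "target_id", "probe_class",
                                       "start", "seq"])


def _slide_n_free(seq: str, start: int, L: int, used: list[int]) -> int | None:
    """Nearest start >= no-overlap constraint whose window is N-free."""
    n = len(seq)
    def ok(s: int) -> bool:
        return (0 <= s <= n - L and "N" not in seq[s:s + L]
                and all(abs(s - u) >= L for u in used))
    if ok(start):
        return start
    for off in range(1, n):
        for s in (start + off, start - off):
            if ok(s):
                return s
        if start + off > n and start - off < 0:
            break
    return None


def probe_accounting(manifest: pd.DataFrame) -> dict:
    """Per-class probe counts plus the per-contig allocation histogram."""
    by_class = manifest["probe_class"].value_counts().to_dict()
    contig_alloc = (manifest[manifest["probe_class"] == "contig"]
                    .groupby("target_id").size().value_counts().to_dict())
    return {"by_class": by_class,
            "total": int(len(manifest)),
            "contigs_by_probe_count": {int(k): int(v)
                                       for k, v in contig_alloc.items()}}


def generate_random_probes(sequences: Sequence[SequenceRecord] | Sequence[str],
                           n: int = 2604,
                           order: int = 1,
                           rng_seed: int = 0,
                           probe_length: int = 60) -> list[str]:
    """Sample n 60-mers from an order-k Markov chain fitted to the input
    nucleotide composition (the 'random probe' null design).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    seqs = [s.seq if isinstance(s, SequenceRecord) else s for s in sequences]
    seqs = [s.upper() for s in seqs if s]
    if not seqs or not any(len(s) > order for s in seqs):
        raise ValueError("empty or too-short training input for Markov model")

    alphabet = "ACGT"
    idx = {b: i for i, b in enumerate(alphabet)}
    rng = np.random.default_rng(rng_seed)

    # transition counts: context (k-mer) -> next-base counts
    counts: dict[str, np.ndarray] = {}
    initial = np.zeros(4)
    for s in seqs:
        s = "".join(b for b in s if b in idx)
        for b in s[: order if order else 1]:
            initial[idx[b]] += 1
        for i in range(order, len(s)):
            ctx = s[i - order:i]
            counts.setdefault(ctx, np.zeros(4))[idx[s[i]]] += 1
            initial[idx[s[i]]] += 1
    base_freq = initial / initial.sum()

    def next_dist(ctx: str) -> np.ndarray:
        c = counts.get(ctx)
        if c is None or c.sum() == 0:
            return base_freq
        return c / c.sum()

    probes = []
    for _ in range(n):
        chars = [alphabet[rng.choice(4, p=base_freq)] for _ in range(order)]
        if order == 0:
            chars = []
        while len(chars) < probe_length:
            ctx = "".join(chars[-order:]) if order else ""
            chars.append(alphabet[rng.choice(4, p=next_dist(ctx))])
        probes.append("".join(chars))
    return probes


def individual_threshold(matrix: pd.DataFrame,
                         manifest: pd.DataFrame,
                         individual: str,
                         quantile: float = 0.975) -> float:
    """Empirical quantile of the individual's random-probe scores
    (linear interpolation between order statistics, the 'type 7' estimator).
    """
    random_ids = manifest.loc[manifest["probe_class"] == "random", "probe_id"]
    scores = matrix.loc[matrix.index.intersection(random_ids), individual].dropna()
    if scores.empty:
        raise ValueError(f"no random-probe scores for individual {individual!r}")
    if len(scores) < 40:
        log.warning("individual %s: only %d random probes; quantile may be unstable",
                    individual, len(scores))
    return float(np.quantile(scores.to_numpy(), quantile, method="linear"))


def call_unit(matrix: pd.DataFrame,
              manifest: pd.DataFrame,
              design: pd.DataFrame,
              unit_id: str,
              group: tuple[str, str],
              cfg: PipelineConfig | None = None,
              thresholds: Mapping[str, float] | None = None) -> ExpressionCall:
    """Call one unit in one tissue-sex group.

    Per individual the statistic is the median of the unit's probe scores
    (the single value for one-probe units); the individual is called iff
    the statistic is strictly above its own random-probe threshold, and the
    group is called iff at least ``expr_min_individuals`` of its individuals
    are called.
    """
    cfg = cfg or PipelineConfig()
    probe_ids = manifest.loc[manifest["target_id"] == unit_id, "probe_id"]
    if probe_ids.empty:
        raise ValueError(f"unit {unit_id!r} absent from probe manifest")
    tissue, sex = group
    individuals = design.loc[(design["tissue"] == tissue) & (design["sex"] == sex),
                             "individual"].tolist()
    n_called = 0
    for ind in individuals:
        thr = (thresholds[ind] if thresholds is not None
               else individual_threshold(matrix, manifest, ind, cfg.expr_null_quantile))
        stat = float(matrix.loc[matrix.index.intersection(probe_ids), ind].median())
        if stat > thr:
            n_called += 1
    return ExpressionCall(unit_id=unit_id, group=group, n_called=n_called,
                          called=n_called >= cfg.expr_min_individuals)


def call_all(matrix: pd.DataFrame,
             manifest: pd.DataFrame,
             design: pd.DataFrame,
             cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Vectorized expression calls for every target unit in every group.

    Returns a tidy frame (unit_id, tissue, sex, n_called, called) plus an
    ``any_group_called`` column marking units expressed in at least one
    tissue-sex combination.
    """
    cfg = cfg or PipelineConfig()
    thresholds = {ind: individual_threshold(matrix, manifest, ind,
                                            cfg.expr_null_quantile)
                  for ind in design["individual"]}
    targets = manifest.dropna(subset=["target_id"])
    # median probe score per unit per individual
    scored = matrix.join(targets.set_index("probe_id")["target_id"], how="inner")
    med = scored.groupby("target_id").median()
    thr = pd.Series(thresholds)
    called = med[thr.index] > thr  # units x individuals, strict >

    rows = []
    for (tissue, sex), sub in design.groupby(["tissue", "sex"]):
        inds = sub["individual"].tolist()
        n = called[inds].sum(axis=1)
        for unit, k in n.items():
            rows.append((unit, tissue, sex, int(k), k >= cfg.expr_min_individuals))
    out = pd.DataFrame(rows, columns=["unit_id", "tissue", "sex", "n_called",
                                      "called"])
    any_called = out.groupby("unit_id")["called"].any()
    out["any_group_called"] = out["unit_id"].map(any_called)
    return out


def replication_pvalue(n: int, k: int, p: float) -> float:
    """Exact binomial tail P(X >= k | n, p): the chance that a null probe is
    called in at least k of n individuals when each call has probability p.
    """
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    if not (1 <= k <= n):
        raise ValueError("require 1 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p))
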