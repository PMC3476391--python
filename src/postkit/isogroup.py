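"""Isogroup clustering and isotig enumeration from broken-read contig graphs.

A 454 de novo assembler splits transcripts into multiple contigs wherever
isoforms or alleles diverge, and records the reads whose alignments were
broken across a contig boundary.  Contigs joined by such broken reads form
a connected "contig graph"; each connected component is an isogroup (a
putative gene) and each maximal link-supported simple path through the
component is an isotig (a putative transcript, e.g. one splice form).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger("postkit")


@dataclass
class Contig:
    id: str
    length: int
    depth: float = 0.0
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id}: length must be >= 1")
        if self.depth < 0:
            raise ValueError(f"contig {self.id}: depth must be >= 0")


@dataclass
class BrokenReadLink:
    read_id: str
    contig_a: str
    contig_b: str
    orientation: str = ""  # 'forward' (a precedes b), 'reverse' (b precedes a), or ''

    def __post_init__(self) -> None:
        if self.contig_a == self.contig_b:
            raise ValueError(f"link {self.read_id}: self-link on {self.contig_a}")


@dataclass
class ContigGraph:
    contigs: dict[str, Contig]
    links: list[BrokenReadLink]

    def __post_init__(self) -> None:
        for l in self.links:
            for end in (l.contig_a, l.contig_b):
                if end not in self.contigs:
                    raise ValueError(f"link {l.read_id} references unknown contig {end}")

    @property
    def oriented(self) -> bool:
        """True when every link carries an orientation."""
        return bool(self.links) and all(l.orientation in ("forward", "reverse")
                                        for l in self.links)


@dataclass
class Isotig:
    id: str
    contig_ids: list[str]
    length: int  # sum of member contig lengths


@dataclass
class Isogroup:
    id: str
    contig_ids: set[str]
    isotigs: list[Isotig] = field(default_factory=list)
    truncated: bool = False


def read_links(path: str | Path) -> list[BrokenReadLink]:
    """Read a broken-read link TSV: read_id, contig_a, contig_b[, orientation]."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["read_id", "contig_a", "contig_b", "orientation"])
    return [BrokenReadLink(r.read_id, r.contig_a, r.contig_b,
                           r.orientation if isinstance(r.orientation, str) else "")
            for r in df.itertuples(index=False)]


def cluster_isogroups(graph: ContigGraph) -> list[Isogroup]:
    """Partition contigs into isogroups = connected components of the link graph.

    Links are treated as undirected for clustering.  Contigs with no links
    form singleton isogroups.  Isogroups are numbered in order of their
    lexicographically smallest member so that output is deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.contigs)
    g.add_edges_from((l.contig_a, l.contig_b) for l in graph.links)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [Isogroup(id=f"isogroup{i:05d}", contig_ids=set(c))
            for i, c in enumerate(comps, start=1)]


def _maximal_simple_paths(nodes: Sequence[str], succ: dict[str, set[str]],
                          pred: dict[str, set[str]], cap: int,
                          undirected: bool) -> tuple[list[tuple[str, ...]], bool]:
    """All maximal simple paths by DFS from every possible head node.

    A path is maximal when neither endpoint can be extended by a node
    outside the path.  ``cap`` bounds the number of paths collected; hitting
    it sets the truncation flag.
    """
    found: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    truncated = False

    def dfs(path: list[str], in_path: set[str]) -> None:
        nonlocal truncated
        if truncated:
            return
        ext = [v for v in sorted(succ[path[-1]]) if v not in in_path]
        if not ext:
            if all(p in in_path for p in pred[path[0]]):
                t = tuple(path)
                if undirected:
                    t = min(t, t[::-1])
                if t not in seen:
                    seen.add(t)
                    found.append(t)
                    if len(found) > cap:
                        truncated = True
            return
        for v in ext:
            path.append(v)
            in_path.add(v)
            dfs(path, in_path)
            in_path.remove(v)
            path.pop()

    for start in sorted(nodes):
        dfs([start], {start})
        if truncated:
            break
    return found, truncated


def enumerate_isotigs(group: Isogroup, graph: ContigGraph,
                      max_isotigs: int = 100) -> list[Isotig]:
    """Enumerate link-supported maximal simple paths of an isogroup as isotigs.

    When every link carries an orientation the graph is traversed as a
    directed graph (forward = contig_a precedes contig_b); otherwise paths
    are enumerated in the undirected graph and canonicalized by their
    lexicographically smaller endpoint.  Cycles terminate paths (isotigs are
    simple paths only) and trigger a warning.  Enumeration stops, with
    ``group.truncated`` set, once ``max_isotigs`` paths have been collected.
    """
    members = sorted(group.contig_ids)
    links = [l for l in graph.links
             if l.contig_a in group.contig_ids and l.contig_b in group.contig_ids]
    directed = bool(links) and all(l.orientation in ("forward", "reverse") for l in links)

    succ: dict[str, set[str]] = {c: set() for c in members}
    pred: dict[str, set[str]] = {c: set() for c in members}
    for l in links:
        a, b = l.contig_a, l.contig_b
        if directed and l.orientation == "reverse":
            a, b = b, a
        succ[a].add(b)
        pred[b].add(a)
        if not directed:
            succ[b].add(a)
            pred[a].add(b)

    if directed:
        dg = nx.DiGraph((a, b) for a in succ for b in succ[a])
        dg.add_nodes_from(members)
        if not nx.is_directed_acyclic_graph(dg):
            log.warning("isogroup %s: cycle in oriented contig graph; "
                        "isotigs restricted to simple paths", group.id)
    else:
        n_edges = sum(len(s) for s in succ.values()) // 2
        if n_edges >= len(members):
            log.warning("isogroup %s: cycle in contig graph; "
                        "isotigs restricted to simple paths", group.id)

    paths, truncated = _maximal_simple_paths(members, succ, pred,
                                             cap=max_isotigs, undirected=not directed)
    if truncated:
        log.warning("isogroup %s: isotig enumeration truncated at %d paths",
                    group.id, max_isotigs)
        paths = paths[:max_isotigs]
    group.truncated = truncated

    isotigs = []
    for i, p in enumerate(sorted(paths), start=1):
        length = sum(graph.contigs[c].length for c in p)
        isotigs.append(Isotig(id=f"{group.id}_isotig{i:03d}",
                              contig_ids=list(p), length=length))
    group.isotigs = isotigs
    return isotigs


def assembly_stats(contigs: Sequence[Contig],
                   singletons: Sequence,
                   isogroups: Sequence[Isogroup]) -> pd.DataFrame:
    """Summary table: counts, total and mean lengths, isogroup accounting."""
    def _mean(total: float, n: int) -> float:
        if n == 0:
            log.warning("assembly_stats: empty category, mean reported as 0")
            return 0.0
        return total / n

    isotigs = [t for g in isogroups for t in g.isotigs]
    contig_total = sum(c.length for c in contigs)
    singleton_total = sum(len(s) for s in singletons)
    isotig_total = sum(t.length for t in isotigs)
    rows = [
        ("contigs", len(contigs), contig_total, _mean(contig_total, len(contigs))),
        ("singletons", len(singletons), singleton_total,
         _mean(singleton_total, len(singletons))),
        ("isotigs", len(isotigs), isotig_total, _mean(isotig_total, len(isotigs))),
        ("isogroups", len(isogroups), None, None),
        ("isogroups_multi_isotig",
         sum(1 for g in isogroups if len(g.isotigs) > 1), None, None),
    ]
    return pd.DataFrame(rows, columns=["category", "count", "total_length",
                                       "mean_length"])
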