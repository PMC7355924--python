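"""Signed directed signaling networks.

A signaling network is a directed graph whose edges carry a sign: +1 for
activation, -1 for inhibition.  This module parses edge lists (3-column
TSV or SIF), merges lists from several sources into a single network with
an explicit policy for sign conflicts, and computes the structural
quantities the downstream coherency analysis needs: signed and unsigned
adjacency matrices, the giant component, and its diameter and radius.

Gene identifiers are opaque, case-sensitive strings; any symbol/ID mapping
happens upstream.  Node order is fixed lexicographically so adjacency
matrices and every downstream index are reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

ACTIVATION = 1
INHIBITION = -1

#: Default mapping from sign tokens (lower-cased) to {+1, -1}.
DEFAULT_SIGN_VOCAB = {
    "activation": ACTIVATION,
    "activates": ACTIVATION,
    "1": ACTIVATION,
    "+1": ACTIVATION,
    "+": ACTIVATION,
    "inhibition": INHIBITION,
    "inhibits": INHIBITION,
    "-1": INHIBITION,
    "-": INHIBITION,
    "−": INHIBITION,       # unicode minus
    "−1": INHIBITION,
}

CONFLICT_POLICIES = ("ambiguous", "keep_both", "drop")


class EdgeListParseError(ValueError):
    """A row of an edge-list file could not be parsed."""


class SignVocabularyError(ValueError):
    """A sign token is not in the configured vocabulary."""


@dataclass(frozen=True, order=True)
class SignedEdge:
    """One directed, signed causal relationship between two genes."""

    source: str
    target: str
    sign: int
    provenance: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass
class SignedEdgeList:
    """Edges parsed from one source, with an audit of what was dropped.

    The conservation identity ``n_rows == len(edges) + n_duplicates +
    n_self_loops`` holds for every parsed file.
    """

    edges: list[SignedEdge]
    n_rows: int = 0
    n_self_loops: int = 0
    n_duplicates: int = 0
    name: str | None = None

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


@dataclass(frozen=True)
class NetworkMetrics:
    """Structural summary of a network's giant component.

    Diameter and radius are the max and min node eccentricity; by default
    they are measured on the undirected projection of the giant weakly
    connected component, the maximal (safest) reachability horizon.
    """

    n_nodes: int
    diameter: int
    radius: int

    def __post_init__(self) -> None:
        if self.radius > self.diameter:
            raise ValueError("radius cannot exceed diameter")


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv3",
    sign_vocab: dict[str, int] | None = None,
    provenance: str | None = None,
) -> SignedEdgeList:
    """Parse a signed edge list from a tab-separated file.

    Two dialects are accepted: ``tsv3`` (``source\\ttarget\\tsign``) and
    ``sif`` (``source\\trelation\\ttarget``).  A header row matching the
    dialect's column names is skipped; ``#`` comment lines are ignored.
    Self-loops are dropped (and counted), exact duplicates collapse to one
    edge, and unknown sign tokens raise :class:`SignVocabularyError`.
    """
    if dialect not in ("tsv3", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    vocab = {k.lower(): v for k, v in (sign_vocab or DEFAULT_SIGN_VOCAB).items()}
    path = Path(path)
    if provenance is None:
        provenance = path.stem

    edges: list[SignedEdge] = []
    seen: set[tuple[str, str, int]] = set()
    n_rows = n_self = n_dup = 0
    header = ("source", "target", "sign") if dialect == "tsv3" else ("source", "relation", "target")

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            if lineno == 1 and tuple(f.strip().lower() for f in fields) == header:
                continue
            if dialect == "tsv3":
                src, tgt, tok = (f.strip() for f in fields)
            else:
                src, tok, tgt = (f.strip() for f in fields)
            if not src or not tgt:
                raise EdgeListParseError(f"{path}:{lineno}: empty gene identifier")
            n_rows += 1
            if tok.lower() not in vocab:
                raise SignVocabularyError(
                    f"{path}:{lineno}: unknown sign token {tok!r}"
                )
            sign = vocab[tok.lower()]
            if src == tgt:
                n_self += 1
                continue
            key = (src, tgt, sign)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append(SignedEdge(src, tgt, sign, provenance))

    if n_self:
        logger.info("%s: dropped %d self-loop row(s)", path, n_self)
    if n_dup:
        logger.info("%s: collapsed %d duplicate row(s)", path, n_dup)
    return SignedEdgeList(edges, n_rows=n_rows, n_self_loops=n_self,
                          n_duplicates=n_dup, name=path.stem)


class SignedNetwork:
    """A merged signed directed network with fixed lexicographic node order.

    ``S`` is the signed adjacency (entries in {-1, 0, +1}); ``B`` the
    unsigned adjacency (``B == |S|``).  Ordered pairs that carried both
    signs at merge time under the ``ambiguous`` policy are excluded from
    both matrices and recorded in :attr:`ambiguous_pairs`.  Under
    ``keep_both`` the conflicting edges stay in :attr:`edges` (so per-edge
    analyses can still see them) but the matrix cell, which cannot hold
    two signs, is zeroed.
    """

    def __init__(
        self,
        edges: Iterable[SignedEdge],
        ambiguous_pairs: Iterable[tuple[str, str]] = (),
        audit: dict | None = None,
        extra_nodes: Iterable[str] = (),
    ) -> None:
        self.edges: list[SignedEdge] = sorted(set(edges))
        self.ambiguous_pairs: frozenset[tuple[str, str]] = frozenset(ambiguous_pairs)
        self.audit: dict = dict(audit or {})
        nodes = {e.source for e in self.edges} | {e.target for e in self.edges}
        for a, b in self.ambiguous_pairs:
            nodes.update((a, b))
        nodes.update(extra_nodes)
        self.nodes: list[str] = sorted(nodes)
        self.node_index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}

    def __len__(self) -> int:
        return len(self.edges)

    def __repr__(self) -> str:
        return (f"SignedNetwork(n_nodes={len(self.nodes)}, n_edges={len(self.edges)}, "
                f"n_ambiguous={len(self.ambiguous_pairs)})")

    @cached_property
    def edge_signs(self) -> dict[tuple[str, str], int]:
        """Map ordered pair -> sign for pairs carrying exactly one sign."""
        signs: dict[tuple[str, str], set[int]] = {}
        for e in self.edges:
            signs.setdefault(e.pair, set()).add(e.sign)
        return {p: next(iter(s)) for p, s in signs.items() if len(s) == 1}

    @cached_property
    def S(self) -> np.ndarray:
        """Signed adjacency matrix, entries in {-1, 0, +1}."""
        n = len(self.nodes)
        S = np.zeros((n, n), dtype=np.int8)
        for (src, tgt), sign in self.edge_signs.items():
            S[self.node_index[src], self.node_index[tgt]] = sign
        return S

    @cached_property
    def B(self) -> np.ndarray:
        """Unsigned adjacency matrix, ``B == |S|``."""
        return np.abs(self.S)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (src, tgt), sign in self.edge_signs.items():
            g.add_edge(src, tgt, sign=sign)
        return g

    def subnetwork(self, keep: Sequence[str]) -> "SignedNetwork":
        """Induced subnetwork on ``keep`` (ambiguous pairs filtered too)."""
        keep_set = set(keep)
        return SignedNetwork(
            [e for e in self.edges if e.source in keep_set and e.target in keep_set],
            [(a, b) for a, b in self.ambiguous_pairs if a in keep_set and b in keep_set],
            audit=self.audit,
        )

    def giant_component(self) -> "SignedNetwork":
        """Largest weakly connected component; ties broken by smallest
        lexicographic member."""
        if not self.nodes:
            raise ValueError("empty network has no giant component")
        comps = sorted(nx.weakly_connected_components(self.to_digraph()),
                       key=lambda c: (-len(c), min(c)))
        return self.subnetwork(sorted(comps[0]))

    def metrics(self, directed: bool = False) -> NetworkMetrics:
        """Diameter and radius of the giant component.

        With ``directed=True`` eccentricities are computed on the largest
        strongly connected component of the digraph instead of the
        undirected projection.
        """
        gc = self.giant_component()
        g: nx.Graph | nx.DiGraph = gc.to_digraph()
        if directed:
            scc = sorted(nx.strongly_connected_components(g),
                         key=lambda c: (-len(c), min(c)))[0]
            g = g.subgraph(scc).copy()
        else:
            g = g.to_undirected()
        if g.number_of_nodes() < 2:
            raise ValueError("metrics need a giant component with >= 2 nodes")
        ecc = nx.eccentricity(g)
        return NetworkMetrics(n_nodes=len(gc.nodes), diameter=max(ecc.values()),
                              radius=min(ecc.values()))


def merge_edge_lists(
    lists: Sequence[SignedEdgeList],
    conflict_policy: str = "ambiguous",
) -> SignedNetwork:
    """Merge edge lists from several sources into one network.

    An ordered pair that appears with both signs is handled per policy:

    * ``ambiguous`` (default): excluded from the signed analyses and
      recorded in the ambiguous-pair set,
    * ``keep_both``: both signed edges retained in the edge set (matrix
      entry zeroed),
    * ``drop``: silently removed (counted in the audit).

    Audit counts satisfy ``n_rows == n_edges + n_duplicates + n_self_loops
    + 2 * n_ambiguous`` under the default policy.
    """
    if not lists:
        raise ValueError("merge_edge_lists needs at least one edge list")
    if conflict_policy not in CONFLICT_POLICIES:
        raise ValueError(f"unknown conflict policy {conflict_policy!r}")

    n_rows = sum(el.n_rows for el in lists)
    n_self = sum(el.n_self_loops for el in lists)
    n_dup = sum(el.n_duplicates for el in lists)

    merged: dict[tuple[str, str, int], SignedEdge] = {}
    for el in lists:
        for e in el.edges:
            key = (e.source, e.target, e.sign)
            if key in merged:
                n_dup += 1          # same signed edge from two sources
            else:
                merged[key] = e

    by_pair: dict[tuple[str, str], list[SignedEdge]] = {}
    for e in merged.values():
        by_pair.setdefault(e.pair, []).append(e)

    edges: list[SignedEdge] = []
    ambiguous: list[tuple[str, str]] = []
    n_conflict_dropped = 0
    for pair, pair_edges in by_pair.items():
        if len(pair_edges) == 1:
            edges.append(pair_edges[0])
        elif conflict_policy == "ambiguous":
            ambiguous.append(pair)
            logger.info("ambiguous sign for pair %s -> excluded", pair)
        elif conflict_policy == "keep_both":
            edges.extend(pair_edges)
        else:  # drop
            n_conflict_dropped += len(pair_edges)

    audit = {
        "n_rows": n_rows,
        "n_self_loops": n_self,
        "n_duplicates": n_dup,
        "n_ambiguous_pairs": len(ambiguous),
        "n_conflict_dropped": n_conflict_dropped,
        "conflict_policy": conflict_policy,
    }
    return SignedNetwork(edges, ambiguous, audit=audit)


def write_edge_list(net: SignedNetwork, path: str | Path,
                    ambiguous_path: str | Path | None = None) -> None:
    """Export the merged network as 3-column TSV (+ ambiguous pairs TSV)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("source\ttarget\tsign\n")
        for e in sorted(net.edges):
            token = "activation" if e.sign == ACTIVATION else "inhibition"
            fh.write(f"{e.source}\t{e.target}\t{token}\n")
    if ambiguous_path is not None:
        with Path(ambiguous_path).open("w") as fh:
            fh.write("source\ttarget\n")
            for a, b in sorted(net.ambiguous_pairs):
                fh.write(f"{a}\t{b}\n")
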