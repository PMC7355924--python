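"""Subgraph census via adjacency-matrix self-multiplication, and the
unconnected-gene-pair (UGP) null.

The k-th power of the signed adjacency S sums the sign products of all
directed walks of length k between two nodes, while the same power of the
unsigned adjacency B counts those walks.  When the two agree in magnitude,
every length-k walk carries the same net sign, and the pair can be given
a single indirect-influence sign.  Walks (which may revisit nodes), not
simple paths, are counted: matrix self-multiplication is the method.

Classes
-------
Dual loops join pairs connected directly in both orientations: DPFBL1
(both activating), DPFBL2 (both inhibiting), DNFBL (mixed signs, a
negative loop).  Multi-edge classes join a direct edge of sign s_d with
the shortest indirect walk (length 2..horizon): a return walk target->
source makes a feedback loop, a parallel walk source->target a
feed-forward loop.  Names follow loop-sign logic (product of the two leg
signs): negative loops are MNFBL/MNFFL, positive/coherent ones
MPFBL/MFFL, with suffix 1 for an activating and 2 for an inhibiting
direct edge.  The (s_d, s_p) -> label map is a configuration table so an
alternative convention can be swapped in without code changes.

UGPs are unordered pairs with no directed walk in either orientation
(transitive closure of B), used as the study's null class.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionCollection, eligible_pair_mask
from .network import SignedNetwork

logger = logging.getLogger(__name__)

SUBGRAPH_CLASSES = (
    "UGP", "Act", "Inh", "DNFBL", "DPFBL1", "DPFBL2",
    "MNFBL1", "MPFBL1", "MNFBL2", "MPFBL2",
    "MFFL1", "MFFL2", "MNFFL1", "MNFFL2",
)

#: (kind, direct sign, indirect sign) -> Table-1-style class label.
DEFAULT_CLASS_MAP = {
    ("feedback", 1, 1): "MPFBL1",
    ("feedback", 1, -1): "MNFBL1",
    ("feedback", -1, -1): "MPFBL2",
    ("feedback", -1, 1): "MNFBL2",
    ("feedforward", 1, 1): "MFFL1",
    ("feedforward", -1, -1): "MFFL2",
    ("feedforward", 1, -1): "MNFFL1",
    ("feedforward", -1, 1): "MNFFL2",
}

DUAL_CLASSES = ("DNFBL", "DPFBL1", "DPFBL2")


class UGPSamplingError(ValueError):
    """Not enough unconnected eligible pairs to sample from."""


@dataclass(frozen=True)
class SubgraphAssignment:
    """One gene pair assigned to one subgraph class.

    For dual classes ``s_indirect`` holds the reverse direct edge's sign
    and ``k`` is None; for multi classes ``k`` is the shortest qualifying
    indirect-walk length and ``s_indirect`` the unanimous walk sign.
    Pairs whose walks disagree in sign at ``k`` get ``label=None``
    (excluded from class tallies but kept for audit).
    """

    gene_i: str
    gene_j: str
    label: str | None
    kind: str                  # "dual" | "feedback" | "feedforward"
    s_direct: int
    s_indirect: int | str      # +1 / -1 / "mixed"
    k: int | None = None


@dataclass
class UGPSet:
    """One replicate of sampled unconnected gene pairs."""

    replicate: int
    pairs: list[tuple[str, str]]
    seed: int


def signed_power(S: np.ndarray, k: int) -> np.ndarray:
    """k-th power of the signed adjacency: entry (i, j) sums the edge-sign
    products over all directed walks i -> j of length k."""
    if k < 1:
        raise ValueError(f"power k must be >= 1, got {k}")
    return np.linalg.matrix_power(S.astype(np.int64), k)


def unsigned_power(B: np.ndarray, k: int) -> np.ndarray:
    """k-th power of the unsigned adjacency: directed walk counts."""
    if k < 1:
        raise ValueError(f"power k must be >= 1, got {k}")
    return np.linalg.matrix_power(B.astype(np.int64), k)


def reachability(B: np.ndarray, horizon: int) -> np.ndarray:
    """Boolean matrix: (i, j) True iff a directed walk i -> j of length
    <= ``horizon`` exists.  Equals the transitive closure once the horizon
    covers the longest shortest path."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    Bb = B.astype(bool)
    reach = Bb.copy()
    frontier = Bb
    for _ in range(horizon - 1):
        frontier = (frontier.astype(np.uint8) @ Bb.astype(np.uint8)) > 0
        new = reach | frontier
        if np.array_equal(new, reach):
            break
        reach = new
    return reach


def transitive_closure(B: np.ndarray) -> np.ndarray:
    """Full directed transitive closure (reachability at any length)."""
    return reachability(B, max(B.shape[0], 1))


def census_dual(net: SignedNetwork) -> list[SubgraphAssignment]:
    """Pairs that influence each other directly twice (both orientations),
    read straight off the edge list."""
    signs = net.edge_signs
    out: list[SubgraphAssignment] = []
    for (a, b), s_ab in sorted(signs.items()):
        if a >= b or (b, a) not in signs:
            continue
        s_ba = signs[(b, a)]
        if s_ab == s_ba == 1:
            label = "DPFBL1"
        elif s_ab == s_ba == -1:
            label = "DPFBL2"
        else:
            label = "DNFBL"
        out.append(SubgraphAssignment(a, b, label, "dual", s_ab, s_ba, k=None))
    return out


def census_multi(
    net: SignedNetwork,
    max_len: int | None = None,
    class_map: dict | None = None,
) -> list[SubgraphAssignment]:
    """Multi-edge feedback and feed-forward loops for every direct edge.

    For each ordered pair (i, j) with a direct edge of sign s_d, the
    shortest indirect walk of length k* in [2, max_len] is sought: j => i
    (feedback) and i => j (feed-forward).  The indirect sign is the sign
    of ``signed_power(S, k*)[..]`` when all k*-walks agree
    (|signed| == unsigned count); otherwise the pair is recorded with
    ``s_indirect="mixed"`` and no class label.  ``max_len`` defaults to
    the radius of the network's giant component.
    """
    cmap = class_map or DEFAULT_CLASS_MAP
    if max_len is None:
        max_len = net.metrics().radius
    idx = net.node_index
    S = net.S.astype(np.int64)
    B = net.B.astype(np.int64)
    spow: dict[int, np.ndarray] = {}
    bpow: dict[int, np.ndarray] = {}
    Sk, Bk = S, B
    for k in range(2, max_len + 1):
        Sk, Bk = Sk @ S, Bk @ B
        spow[k], bpow[k] = Sk, Bk

    out: list[SubgraphAssignment] = []
    for (src, tgt), s_d in sorted(net.edge_signs.items()):
        i, j = idx[src], idx[tgt]
        for kind, a, b in (("feedback", j, i), ("feedforward", i, j)):
            for k in range(2, max_len + 1):
                count = bpow[k][a, b]
                if count == 0:
                    continue
                total = spow[k][a, b]
                if abs(total) == count:
                    s_p = 1 if total > 0 else -1
                    out.append(SubgraphAssignment(
                        src, tgt, cmap[(kind, s_d, s_p)], kind, s_d, s_p, k=k))
                else:
                    out.append(SubgraphAssignment(
                        src, tgt, None, kind, s_d, "mixed", k=k))
                break
    return out


def sample_ugp(
    net: SignedNetwork,
    coll: ExpressionCollection,
    m: int = 1000,
    n_replicates: int = 10,
    seed: int = 0,
    min_n: int = 3,
) -> list[UGPSet]:
    """Sample replicates of unconnected, expression-eligible gene pairs.

    Candidates are unordered node pairs with no directed walk in either
    orientation (transitive closure of the unsigned adjacency, so the
    horizon exceeds any diameter) that are eligible in at least one
    expression dataset.  Replicate seeds derive deterministically from the
    master seed; pairs are distinct within a replicate.
    """
    closure = transitive_closure(net.B)
    unconnected = ~closure & ~closure.T
    eligible = eligible_pair_mask(coll, net.nodes, min_n=min_n)
    n = len(net.nodes)
    iu = np.triu_indices(n, k=1)
    ok = unconnected[iu] & eligible[iu]
    cand_i, cand_j = iu[0][ok], iu[1][ok]
    n_cand = len(cand_i)
    if n_cand < m:
        raise UGPSamplingError(
            f"need {m} unconnected eligible pairs but only {n_cand} available")

    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    out: list[UGPSet] = []
    for rep, ss in enumerate(child_seeds, start=1):
        rng = np.random.default_rng(ss)
        chosen = rng.choice(n_cand, size=m, replace=False)
        pairs = sorted((net.nodes[cand_i[c]], net.nodes[cand_j[c]]) for c in chosen)
        out.append(UGPSet(rep, pairs, seed=seed))
    return out
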