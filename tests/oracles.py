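"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive — recursive walk enumeration and
plain BFS — so it shares no code path with the matrix-power and
networkx-based implementations it checks.
"""
from __future__ import annotations

from collections import deque


def walk_stats(edges: dict[tuple[int, int], int], start: int, end: int,
               length: int) -> tuple[int, int]:
    """(walk count, sign-product sum) over all directed walks of exactly
    ``length`` from start to end.  ``edges`` maps (i, j) -> sign."""
    succ: dict[int, list[tuple[int, int]]] = {}
    for (i, j), s in edges.items():
        succ.setdefault(i, []).append((j, s))

    def rec(node: int, remaining: int, sign: int) -> tuple[int, int]:
        if remaining == 0:
            return (1, sign) if node == end else (0, 0)
        count = total = 0
        for nxt, s in succ.get(node, []):
            c, t = rec(nxt, remaining - 1, sign * s)
            count += c
            total += t
        return count, total

    return rec(start, length, 1)


def bfs_shortest_paths(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    """Unweighted shortest path lengths from source (plain BFS)."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def bfs_reachable(succ: dict[str, set[str]], source: str) -> set[str]:
    """All nodes reachable from source by a directed path (excl. trivial)."""
    seen: set[str] = set()
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in succ.get(u, ()):
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


def directed_succ(edges) -> dict[str, set[str]]:
    succ: dict[str, set[str]] = {}
    for (i, j) in edges:
        succ.setdefault(i, set()).add(j)
    return succ


def oracle_eccentricities(nodes, edges) -> dict[str, int]:
    """Eccentricities on the undirected projection, by BFS from scratch."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for (i, j) in edges:
        adj[i].add(j)
        adj[j].add(i)
    ecc = {}
    for n in nodes:
        dist = bfs_shortest_paths(adj, n)
        if len(dist) != len(nodes):
            raise ValueError("graph not connected")
        ecc[n] = max(dist.values())
    return ecc


def oracle_census_multi(edge_signs: dict[tuple[str, str], int], nodes: list[str],
                        max_len: int, class_map: dict) -> set[tuple]:
    """Classify every direct edge by explicit walk enumeration.

    Returns tuples (gene_i, gene_j, label_or_None, kind, s_d, s_p, k*).
    """
    idx = {n: i for i, n in enumerate(nodes)}
    int_edges = {(idx[a], idx[b]): s for (a, b), s in edge_signs.items()}
    out = set()
    for (src, tgt), s_d in edge_signs.items():
        for kind, a, b in (("feedback", tgt, src), ("feedforward", src, tgt)):
            for k in range(2, max_len + 1):
                count, total = walk_stats(int_edges, idx[a], idx[b], k)
                if count == 0:
                    continue
                if abs(total) == count:
                    s_p = 1 if total > 0 else -1
                    out.add((src, tgt, class_map[(kind, s_d, s_p)],
                             kind, s_d, s_p, k))
                else:
                    out.add((src, tgt, None, kind, s_d, "mixed", k))
                break
    return out
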