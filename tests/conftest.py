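from __future__ import annotations

import numpy as np
import pytest

import coherenet as cn


def make_network(edge_tuples) -> cn.SignedNetwork:
    """SignedNetwork from (source, target, sign) tuples."""
    return cn.SignedNetwork([cn.SignedEdge(a, b, s) for a, b, s in edge_tuples])


def random_signed_graph(rng: np.random.Generator, n_nodes: int,
                        n_edges: int) -> cn.SignedNetwork:
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    n_edges = min(n_edges, n_nodes * (n_nodes - 1))
    edges: dict[tuple[str, str], int] = {}
    while len(edges) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            edges[(nodes[i], nodes[j])] = 1 if rng.random() < 0.6 else -1
    return make_network([(a, b, s) for (a, b), s in edges.items()])


@pytest.fixture(scope="session")
def small_cfg() -> cn.SimulationConfig:
    """A reduced generator configuration used across the unit tests."""
    return cn.SimulationConfig(n_genes=60, n_edges=70, n_datasets=3,
                               n_dual_pairs=3, n_feedback_triangles=2,
                               n_feedforward_triangles=2, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    net, truth = cn.simulate_network(small_cfg)
    coll = cn.simulate_expression(net, truth, small_cfg)
    degs = cn.simulate_deg_labels(net, truth, small_cfg)
    return net, truth, coll, degs


@pytest.fixture()
def small_bundle(small_cfg, small_sim, tmp_path):
    net, truth, coll, degs = small_sim
    cn.write_bundle(tmp_path, net, truth, coll, degs, small_cfg)
    return tmp_path
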