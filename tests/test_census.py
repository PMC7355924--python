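"""Matrix-power walk census, reachability, and UGP sampling."""
from __future__ import annotations

import numpy as np
import pytest

import coherenet as cn
from coherenet.census import DEFAULT_CLASS_MAP, UGPSamplingError
from conftest import make_network, random_signed_graph
from oracles import bfs_reachable, directed_succ, oracle_census_multi, walk_stats


class TestPowers:
    def test_chain_sign_product(self):
        net = make_network([("A", "B", 1), ("B", "C", -1)])
        a, c = net.node_index["A"], net.node_index["C"]
        assert cn.signed_power(net.S, 2)[a, c] == -1
        assert cn.unsigned_power(net.B, 2)[a, c] == 1

    def test_closed_walk_sign(self):
        net = make_network([("A", "B", 1), ("B", "C", 1), ("C", "A", -1)])
        a = net.node_index["A"]
        assert cn.signed_power(net.S, 3)[a, a] == -1

    def test_invalid_power(self):
        with pytest.raises(ValueError):
            cn.signed_power(np.zeros((2, 2)), 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_walk_enumeration(self, seed):
        """Matrix powers equal explicit recursive walk enumeration."""
        rng = np.random.default_rng(seed)
        net = random_signed_graph(rng, 8, 14)
        idx = net.node_index
        edges = {(idx[a], idx[b]): s for (a, b), s in net.edge_signs.items()}
        for k in (1, 2, 3, 4, 5):
            Sk, Bk = cn.signed_power(net.S, k), cn.unsigned_power(net.B, k)
            for i in range(len(net.nodes)):
                for j in range(len(net.nodes)):
                    count, total = walk_stats(edges, i, j, k)
                    assert Bk[i, j] == count and Sk[i, j] == total


class TestReachability:
    def test_chain(self):
        net = make_network([("A", "B", 1), ("B", "C", 1)])
        r = cn.reachability(net.B, 2)
        idx = net.node_index
        assert r[idx["A"], idx["C"]] and not r[idx["C"], idx["A"]]

    def test_disjoint_components(self):
        net = make_network([("A", "B", 1), ("C", "D", 1)])
        r = cn.transitive_closure(net.B)
        idx = net.node_index
        for a in "AB":
            for b in "CD":
                assert not r[idx[a], idx[b]] and not r[idx[b], idx[a]]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bfs_closure(self, seed):
        rng = np.random.default_rng(seed)
        net = random_signed_graph(rng, 15, 25)
        succ = directed_succ([e.pair for e in net.edges])
        closure = cn.transitive_closure(net.B)
        for a in net.nodes:
            reach = bfs_reachable(succ, a)
            for b in net.nodes:
                assert closure[net.node_index[a], net.node_index[b]] == (b in reach)

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            cn.reachability(np.zeros((2, 2)), 0)


class TestCensusDual:
    @pytest.mark.parametrize("s_ab, s_ba, label", [
        (1, -1, "DNFBL"), (1, 1, "DPFBL1"), (-1, -1, "DPFBL2")])
    def test_sign_combinations(self, s_ab, s_ba, label):
        net = make_network([("A", "B", s_ab), ("B", "A", s_ba)])
        (a,) = cn.census_dual(net)
        assert a.label == label and a.kind == "dual" and a.k is None

    def test_one_way_edge_not_dual(self):
        assert cn.census_dual(make_network([("A", "B", 1)])) == []

    def test_loop_sign_consistency_with_multi_map(self):
        """Dual classes follow the same loop-sign logic as the multi-edge
        feedback map: mixed signs -> negative loop, same signs -> positive."""
        for s_ab, s_ba in ((1, 1), (-1, -1), (1, -1), (-1, 1)):
            net = make_network([("A", "B", s_ab), ("B", "A", s_ba)])
            (a,) = cn.census_dual(net)
            negative_loop = s_ab * s_ba < 0
            assert (a.label == "DNFBL") == negative_loop


class TestCensusMulti:
    def test_feedback_triangle(self):
        net = make_network([("A", "B", 1), ("B", "C", 1), ("C", "A", 1)])
        got = {(a.gene_i, a.gene_j, a.label, a.kind)
               for a in cn.census_multi(net, max_len=2)}
        assert ("A", "B", "MPFBL1", "feedback") in got

    def test_feedforward_mnffl1(self):
        net = make_network([("A", "B", 1), ("A", "C", 1), ("C", "B", -1)])
        multi = [a for a in cn.census_multi(net, max_len=2)
                 if (a.gene_i, a.gene_j) == ("A", "B")]
        (a,) = multi
        assert a.label == "MNFFL1" and a.kind == "feedforward" and a.k == 2

    def test_mixed_signs_excluded(self):
        """Two length-2 return walks of opposite sign: no unanimous
        indirect sign, so the pair is excluded from the class tallies."""
        net = make_network([("A", "B", 1),
                            ("B", "C", 1), ("C", "A", 1),
                            ("B", "D", 1), ("D", "A", -1)])
        fb = [a for a in cn.census_multi(net, max_len=3)
              if (a.gene_i, a.gene_j, a.kind) == ("A", "B", "feedback")]
        (a,) = fb
        assert a.label is None and a.s_indirect == "mixed"

    def test_shortest_length_wins(self):
        # return walks at k=2 (C) and k=3 (D, E); only k=2 counts
        net = make_network([("A", "B", 1), ("B", "C", 1), ("C", "A", -1),
                            ("B", "D", 1), ("D", "E", 1), ("E", "A", 1)])
        fb = [a for a in cn.census_multi(net, max_len=3)
              if (a.gene_i, a.gene_j, a.kind) == ("A", "B", "feedback")]
        (a,) = fb
        assert a.k == 2 and a.label == "MNFBL1"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_signed_graph(rng, int(rng.integers(6, 15)),
                                  int(rng.integers(8, 35)))
        got = {(a.gene_i, a.gene_j, a.label, a.kind, a.s_direct,
                a.s_indirect, a.k) for a in cn.census_multi(net, max_len=5)}
        want = oracle_census_multi(net.edge_signs, net.nodes, 5,
                                   DEFAULT_CLASS_MAP)
        assert got == want

    def test_dual_pairs_also_counted_as_simple_edges(self):
        """Dual-loop pairs keep their Act/Inh membership: classes overlap
        by design."""
        net = make_network([("A", "B", 1), ("B", "A", -1)])
        signs = net.edge_signs
        assert signs[("A", "B")] == 1 and signs[("B", "A")] == -1
        assert len(cn.census_dual(net)) == 1


class TestSampleUGP:
    def test_cross_component_candidates(self, small_sim):
        net = make_network([("A", "B", 1), ("C", "D", 1)])
        coll = self._coll_for(net.nodes)
        sets = cn.sample_ugp(net, coll, m=4, n_replicates=2, seed=1)
        expect = {("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")}
        for us in sets:
            assert set(us.pairs) == expect

    def _coll_for(self, genes, n=6):
        import pandas as pd
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((len(genes), n)),
                          index=list(genes),
                          columns=[f"s{i}" for i in range(n)])
        return cn.ExpressionCollection([cn.ExpressionDataset("d1", df)])

    def test_fully_connected_has_no_ugps(self):
        net = make_network([("A", "B", 1), ("B", "C", 1), ("C", "A", 1)])
        with pytest.raises(UGPSamplingError, match="0 available"):
            cn.sample_ugp(net, self._coll_for(net.nodes), m=1, n_replicates=1,
                          seed=0)

    def test_seed_reproducible(self):
        net = make_network([("A", "B", 1), ("C", "D", 1), ("E", "F", -1)])
        coll = self._coll_for(net.nodes)
        a = cn.sample_ugp(net, coll, m=5, n_replicates=3, seed=42)
        b = cn.sample_ugp(net, coll, m=5, n_replicates=3, seed=42)
        assert [u.pairs for u in a] == [u.pairs for u in b]
        c = cn.sample_ugp(net, coll, m=5, n_replicates=3, seed=43)
        assert [u.pairs for u in a] != [u.pairs for u in c]

    def test_no_directed_path_by_bfs(self, small_sim):
        """Independent BFS check: sampled pairs are unreachable in both
        orientations."""
        net, _, coll, _ = small_sim
        gc = net.giant_component()
        sets = cn.sample_ugp(gc, coll, m=30, n_replicates=2, seed=7)
        succ = directed_succ([e.pair for e in gc.edges])
        for us in sets:
            assert len(set(us.pairs)) == len(us.pairs)
            for a, b in us.pairs:
                assert b not in bfs_reachable(succ, a)
                assert a not in bfs_reachable(succ, b)
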