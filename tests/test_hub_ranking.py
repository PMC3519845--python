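"""Hub scoring: BFS trees, BN vs brute-force oracle, MNC/DMNC/DSS properties."""

from __future__ import annotations

import random

import networkx as nx
import pytest

from fgnet.hub_ranking import (
    DSSConfig,
    bn_scores,
    build_sp_tree,
    degree_scores,
    dmnc_scores,
    dss_rank,
    mnc_scores,
    top_k,
)
from fgnet.synthetic_data import SimConfig, plant_bottlenecks

from conftest import make_network, oracle_bn, random_connected_graph


class TestBuildSpTree:
    def test_path_tree(self):
        net = make_network([("a", "b"), ("b", "c")])
        tree = build_sp_tree(net, "a")
        assert tree.parent == {"b": "a", "c": "b"}
        assert tree.subtree_weight == {"a": 2, "b": 1, "c": 0}
        assert tree.n_tree == 3

    def test_square_lexicographic_tie_break(self):
        # a-b, b-c, a-d, d-c: c has predecessors {b, d} at depth 1 -> parent b
        net = make_network([("a", "b"), ("b", "c"), ("a", "d"), ("d", "c")])
        tree = build_sp_tree(net, "a")
        assert tree.parent["c"] == "b"
        assert tree.subtree_weight["b"] == 1 and tree.subtree_weight["d"] == 0

    def test_isolated_root(self):
        net = make_network([("a", "b")], nodes=["z"])
        tree = build_sp_tree(net, "z")
        assert tree.n_tree == 1 and not tree.parent

    def test_depth_consistency_and_root_weight(self):
        g = random_connected_graph(random.Random(5), max_n=12)
        tree = build_sp_tree(g, sorted(g.nodes)[0])
        for child, p in tree.parent.items():
            assert tree.depth[child] == tree.depth[p] + 1
        assert tree.subtree_weight[tree.root] == tree.n_tree - 1

    def test_unknown_root_rejected(self):
        with pytest.raises(ValueError):
            build_sp_tree(make_network([("a", "b")]), "q")


class TestBnScores:
    def test_path_p3(self):
        net = make_network([("a", "b"), ("b", "c")])
        assert bn_scores(net).score == {"a": 0, "b": 2, "c": 0}

    @pytest.mark.parametrize("m", [2, 4, 7])
    def test_star_center_scores_m(self, m):
        net = make_network([("c", f"l{i}") for i in range(m)])
        score = bn_scores(net).score
        assert score["c"] == m
        assert all(score[f"l{i}"] == 0 for i in range(m))

    def test_edgeless_graph_all_zero(self):
        net = make_network([], nodes=["a", "b", "c"])
        assert set(bn_scores(net).score.values()) == {0}

    def test_matches_brute_force_oracle_on_random_graphs(self):
        """Exact agreement with an independent per-root tree enumeration on
        200 random connected graphs of up to 12 nodes."""
        rng = random.Random(20240917)
        for _ in range(200):
            g = random_connected_graph(rng, max_n=12)
            assert bn_scores(g).score == oracle_bn(g)

    def test_disconnected_components_scored_independently(self):
        net = make_network([("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")])
        score = bn_scores(net).score
        assert score["b"] == 2 and score["y"] == 2
        assert score["a"] == score["x"] == 0


class TestMncDmnc:
    def test_complete_graph_k4(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        assert set(mnc_scores(g).score.values()) == {3.0}
        for v, s in dmnc_scores(g).score.items():
            assert s == pytest.approx(3 / 3**1.7, abs=1e-9)

    def test_star_center(self):
        net = make_network([("c", f"l{i}") for i in range(5)])
        assert mnc_scores(net).score["c"] == 1.0
        assert dmnc_scores(net).score["c"] == 0.0

    def test_isolated_node_scores_zero(self):
        net = make_network([], nodes=["a"])
        assert mnc_scores(net).score["a"] == 0.0
        assert dmnc_scores(net).score["a"] == 0.0

    def test_pendant_on_triangle(self):
        net = make_network([("a", "b"), ("b", "c"), ("a", "c"), ("c", "p")])
        assert dmnc_scores(net).score["p"] == 0.0  # single-node component
        assert mnc_scores(net).score["p"] == 1.0

    def test_mnc_bounded_by_degree_property(self):
        rng = random.Random(7)
        for _ in range(30):
            g = random_connected_graph(rng, max_n=15)
            mnc = mnc_scores(g).score
            deg = degree_scores(g).score
            assert all(mnc[v] <= deg[v] for v in g.nodes)

    def test_dmnc_zero_iff_mnc_edgeless(self):
        rng = random.Random(8)
        for _ in range(30):
            g = random_connected_graph(rng, max_n=12)
            dmnc = dmnc_scores(g).score
            for v in g.nodes:
                sub = g.subgraph(list(g.neighbors(v)))
                comps = list(nx.connected_components(sub)) if sub else []
                max_edges = max(
                    (sub.subgraph(c).number_of_edges() for c in comps), default=0
                )
                assert (dmnc[v] == 0.0) == (max_edges == 0)


class TestDegree:
    def test_triangle_and_star(self, triangle):
        assert set(degree_scores(triangle).score.values()) == {2.0}
        net = make_network([("c", f"l{i}") for i in range(4)])
        assert degree_scores(net).score["c"] == 4.0

    def test_planted_hub_degree(self):
        net = make_network([("HUB", f"n{i:03d}") for i in range(117)])
        assert degree_scores(net).score["HUB"] == 117.0


class TestDssRank:
    @pytest.mark.parametrize("seed", range(20))
    def test_construction_property(self, seed):
        """Output ⊆ top-2n DMNC pool, size min(n, pool), ordered by MNC."""
        g = random_connected_graph(random.Random(seed), max_n=15)
        cfg = DSSConfig(n_out=3)
        table = dss_rank(g, cfg)
        dmnc = dmnc_scores(g)
        mnc = mnc_scores(g)
        pool = dmnc.rank_order[: min(2 * cfg.n_out, g.number_of_nodes())]
        assert set(table.rank_order) <= set(pool)
        assert len(table.rank_order) == min(cfg.n_out, len(pool))
        scores = [mnc.score[v] for v in table.rank_order]
        assert scores == sorted(scores, reverse=True)

    def test_second_screen_rescues_high_mnc_node(self):
        """A node outside the DMNC top-n but with maximal MNC must surface
        in the DSS output: two K4 cliques outscore the wheel hub on DMNC,
        yet the wheel hub has the largest neighbourhood component."""
        edges = []
        for base in ("p", "q"):  # two disjoint K4s
            ids = [f"{base}{i}" for i in range(4)]
            edges += [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        cyc = [f"c{i}" for i in range(5)]  # wheel: hub x + 5-cycle
        edges += list(zip(cyc, cyc[1:] + cyc[:1]))
        edges += [("x", c) for c in cyc]
        net = make_network(edges)

        n_out = 5
        dmnc = dmnc_scores(net)
        assert dmnc.rank_order.index("x") >= n_out  # single screen would drop x
        assert mnc_scores(net).score["x"] == max(mnc_scores(net).score.values())
        out = dss_rank(net, DSSConfig(n_out=n_out))
        assert out.rank_order[0] == "x"

    def test_n_out_covers_all_nodes(self, triangle):
        table = dss_rank(triangle, DSSConfig(n_out=10))
        assert len(table.rank_order) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_relabeling_equivariance(self, seed):
        """Relabeling nodes and mapping the output back reproduces the
        original ranking (the relabeling preserves lexicographic order, so
        id-based tie-breaks resolve identically)."""
        g = random_connected_graph(random.Random(seed), max_n=10)
        mapping = {v: f"z{i:03d}" for i, v in enumerate(sorted(g.nodes))}
        h = nx.relabel_nodes(g, mapping)
        out_g = dss_rank(g, DSSConfig(n_out=3))
        out_h = dss_rank(h, DSSConfig(n_out=3))
        inverse = {w: v for v, w in mapping.items()}
        assert [inverse[w] for w in out_h.rank_order] == out_g.rank_order
        assert {inverse[w]: s for w, s in out_h.score.items()} == out_g.score


class TestTopK:
    def test_tie_broken_by_id(self):
        from fgnet.hub_ranking import HubScoreTable

        table = HubScoreTable("degree", {"A": 3.0, "B": 3.0, "C": 1.0})
        assert top_k(table, 2) == ["A", "B"]

    def test_star_center_first_for_degree_and_bn(self):
        net = make_network([("c", f"l{i}") for i in range(4)])
        assert top_k(degree_scores(net), 1) == ["c"]
        assert top_k(bn_scores(net), 1) == ["c"]

    def test_k_beyond_size_returns_all_with_warning(self, triangle, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = top_k(degree_scores(triangle), 10)
        assert len(out) == 3
        assert any("exceeds" in r.message for r in caplog.records)


class TestPlantedConnectorRecovery:
    def test_connector_is_top_bn_and_removal_disconnects(self):
        """On 2×15-node clusters joined by one connector, BN must rank the
        connector first and its removal must split the graph (30 seeds)."""
        for seed in range(30):
            cfg = SimConfig(n_clusters=2, cluster_size=15, n_connectors=1, rng_seed=seed)
            net, truth = plant_bottlenecks(cfg)
            (connector,) = truth
            table = bn_scores(net)
            assert table.rank_order[0] == connector, f"seed {seed}"
            g = net.to_graph()
            g.remove_node(connector)
            assert not nx.is_connected(g), f"seed {seed}"
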