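"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import networkx as nx
import pytest

from fgnet.core_io import InteractionNetwork, Node, Relation


def make_network(edges, nodes=(), name="test") -> InteractionNetwork:
    """Build a network of undirected binding relations from (u, v) pairs."""
    net = InteractionNetwork(name)
    for n in nodes:
        net.add_node(n)
    for u, v in edges:
        net.add_relation(Relation(u, v, "binding"), create_nodes=True)
    return net


def random_connected_graph(rng: random.Random, max_n: int = 12) -> nx.Graph:
    """A random connected labelled graph with 2..max_n nodes."""
    n = rng.randint(2, max_n)
    p = rng.uniform(0.2, 0.8)
    while True:
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
        if nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes})


# ---------------------------------------------------------------------
# independent bottleneck-score oracle: explicit per-root layered BFS with
# the lexicographic parent rule and explicit recursive descendant counting.
# Shares no code with fgnet.hub_ranking.
# ---------------------------------------------------------------------

def oracle_bfs_tree(g: nx.Graph, root):
    """(parent map, layers) of the BFS tree with lexicographically minimal parents."""
    layers = [[root]]
    parent = {}
    visited = {root}
    while True:
        nxt = {}
        for u in layers[-1]:
            for v in g.neighbors(u):
                if v in visited:
                    continue
                if v not in nxt or u < nxt[v]:
                    nxt[v] = u
        if not nxt:
            break
        for v, p in nxt.items():
            parent[v] = p
            visited.add(v)
        layers.append(sorted(nxt))
    return parent, layers


def oracle_descendants(parent, node) -> int:
    """Strict descendant count by explicit child expansion."""
    children = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    count = 0
    stack = list(children.get(node, []))
    while stack:
        w = stack.pop()
        count += 1
        stack.extend(children.get(w, []))
    return count


def oracle_bn(g: nx.Graph) -> dict:
    """Brute-force bottleneck scores over every root's tree."""
    score = {v: 0 for v in g.nodes}
    for root in g.nodes:
        parent, _ = oracle_bfs_tree(g, root)
        n_tree = len(parent) + 1
        for w in parent:  # every non-root tree node
            if oracle_descendants(parent, w) >= n_tree / 4:
                score[w] += 1
    return score


@pytest.fixture
def triangle() -> InteractionNetwork:
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def chain4() -> InteractionNetwork:
    """Path a - b - c - d."""
    return make_network([("a", "b"), ("b", "c"), ("c", "d")])
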