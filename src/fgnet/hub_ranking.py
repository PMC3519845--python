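"""Topological essentiality scoring: Degree, BN, MNC, DMNC and the DSS scheme.

All scores run on the undirected simple topology of an interaction network.

**Bottleneck (BN).**  For every node ``v`` a breadth-first shortest-path tree
``Tv`` rooted at ``v`` is built over ``v``'s connected component.  The weight
of a node ``w`` in ``Tv`` is its number of strict descendants — equivalently
the number of shortest paths from ``v`` that pass through ``w``.  ``w`` is a
bottleneck in ``Tv`` when its weight is at least ``n/4`` (``n`` = tree size,
real-valued threshold, inclusive).  BN(w) counts the roots ``v`` for which
``w`` qualifies.  The root itself is never counted in its own tree: its
``n − 1`` descendants would qualify trivially and carry no information.
Shortest-path trees are not unique, so determinism is pinned by a tie-break:
a node's parent is its lexicographically smallest predecessor one level up.

**MNC.**  Size of the largest connected component of the subgraph induced by
the open neighbourhood N(v) (v excluded).

**DMNC.**  Density-style normalisation of that component: E / V**eps with
eps = 1.7 by default; a component with at most one node scores 0.

**DSS.**  Double screening: shortlist the top ``2n`` nodes by DMNC, then
output the top ``n`` of that pool re-ranked by MNC.

Ranking is always by descending score with ties broken by ascending node id
(DSS additionally uses the stage-1 DMNC score as a secondary key), which
makes every table a deterministic total order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .core_io import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ShortestPathTree",
    "HubScoreTable",
    "DSSConfig",
    "build_sp_tree",
    "bn_scores",
    "mnc_scores",
    "dmnc_scores",
    "degree_scores",
    "dss_rank",
    "top_k",
]


@dataclass
class ShortestPathTree:
    """BFS tree rooted at ``root`` with strict-descendant counts."""

    root: str
    parent: dict[str, str]          # child -> parent; root absent
    depth: dict[str, int]           # root at 0
    subtree_weight: dict[str, int]  # strict descendants, excluding the node itself

    @property
    def n_tree(self) -> int:
        return len(self.depth)


@dataclass
class HubScoreTable:
    """Per-node scores for one method plus the deterministic ranked order."""

    method: str
    score: dict[str, float]
    rank_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rank_order:
            self.rank_order = _rank(self.score)
        assert sorted(self.rank_order) == sorted(self.score), "rank_order must permute scored nodes"


@dataclass(frozen=True)
class DSSConfig:
    """Output size ``n_out`` and screening factor (pool = screen_factor·n_out)."""

    n_out: int = 30
    screen_factor: int = 2

    def __post_init__(self) -> None:
        if self.n_out < 1:
            raise ValueError("n_out must be ≥ 1")
        if self.screen_factor < 1:
            raise ValueError("screen_factor must be ≥ 1")


def _rank(score: dict[str, float], secondary: dict[str, float] | None = None) -> list[str]:
    """Descending score, then descending secondary score, then ascending id."""
    if secondary is None:
        return sorted(score, key=lambda n: (-score[n], n))
    return sorted(score, key=lambda n: (-score[n], -secondary[n], n))


def build_sp_tree(net: InteractionNetwork | nx.Graph, root: str) -> ShortestPathTree:
    """Deterministic BFS shortest-path tree over the root's component.

    When a node has several predecessors on the previous BFS level, its
    parent is the lexicographically smallest; weights are strict descendant
    counts accumulated bottom-up.
    """
    g = net.to_graph() if isinstance(net, InteractionNetwork) else net
    if root not in g:
        raise ValueError(f"unknown root {root!r}")
    depth: dict[str, int] = {root: 0}
    parent: dict[str, str] = {}
    frontier = [root]
    while frontier:
        nxt: dict[str, str] = {}
        for u in sorted(frontier):
            for v in g.neighbors(u):
                if v in depth:
                    continue
                best = nxt.get(v)
                if best is None or u < best:
                    nxt[v] = u
        for v, p in nxt.items():
            parent[v] = p
            depth[v] = depth[p] + 1
        frontier = list(nxt)
    weight = {n: 0 for n in depth}
    for child in sorted(depth, key=depth.get, reverse=True):
        if child == root:
            continue
        p = parent[child]
        weight[p] += weight[child] + 1
    return ShortestPathTree(root=root, parent=parent, depth=depth, subtree_weight=weight)


def bn_scores(net: InteractionNetwork | nx.Graph) -> HubScoreTable:
    """Bottleneck scores: roots whose tree makes each node a ≥ n/4 gatekeeper.

    Trees never cross components; an isolated node scores 0 everywhere.
    """
    g = net.to_graph() if isinstance(net, InteractionNetwork) else net
    score: dict[str, float] = {n: 0 for n in g.nodes}
    for v in g.nodes:
        tree = build_sp_tree(g, v)
        threshold = tree.n_tree / 4.0
        for w, wt in tree.subtree_weight.items():
            if w != v and wt >= threshold:
                score[w] += 1
    return HubScoreTable("bn", score)


def _mnc_component(g: nx.Graph, v: str) -> tuple[int, int]:
    """(node count, edge count) of v's maximum neighbourhood component."""
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return 0, 0
    sub = g.subgraph(nbrs)
    best_nodes: set[str] = set()
    for comp in nx.connected_components(sub):
        if len(comp) > len(best_nodes):
            best_nodes = comp
    comp_sub = sub.subgraph(best_nodes)
    return comp_sub.number_of_nodes(), comp_sub.number_of_edges()


def mnc_scores(net: InteractionNetwork | nx.Graph) -> HubScoreTable:
    """Maximum Neighborhood Component sizes; isolated nodes score 0."""
    g = net.to_graph() if isinstance(net, InteractionNetwork) else net
    score = {v: float(_mnc_component(g, v)[0]) for v in g.nodes}
    return HubScoreTable("mnc", score)


def dmnc_scores(net: InteractionNetwork | nx.Graph, epsilon: float = 1.7) -> HubScoreTable:
    """Density of the Maximum Neighborhood Component: E / V**epsilon.

    A neighbourhood component with V ≤ 1 (hence no edges) scores 0.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    g = net.to_graph() if isinstance(net, InteractionNetwork) else net
    score: dict[str, float] = {}
    for v in g.nodes:
        n_v, e_v = _mnc_component(g, v)
        score[v] = 0.0 if n_v <= 1 else e_v / n_v**epsilon
    return HubScoreTable("dmnc", score)


def degree_scores(net: InteractionNetwork | nx.Graph) -> HubScoreTable:
    """Distinct-neighbour counts on the undirected simple topology."""
    g = net.to_graph() if isinstance(net, InteractionNetwork) else net
    return HubScoreTable("degree", {n: float(d) for n, d in g.degree()})


def dss_rank(net: InteractionNetwork | nx.Graph, cfg: DSSConfig = DSSConfig()) -> HubScoreTable:
    """Double screening: DMNC shortlist of 2n, re-ranked by MNC, top n out.

    The returned table's scores are the stage-2 MNC values of the output
    nodes; ties within the pool break by stage-1 DMNC, then node id.
    """
    g = net.to_graph() if isinstance(net, InteractionNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("dss_rank requires at least one node")
    dmnc = dmnc_scores(g)
    mnc = mnc_scores(g)
    pool_size = min(cfg.screen_factor * cfg.n_out, g.number_of_nodes())
    pool = dmnc.rank_order[:pool_size]
    ranked_pool = _rank({v: mnc.score[v] for v in pool}, secondary=dmnc.score)
    out = ranked_pool[: min(cfg.n_out, len(ranked_pool))]
    return HubScoreTable("dss", {v: mnc.score[v] for v in out}, rank_order=out)


def top_k(table: HubScoreTable, k: int) -> list[str]:
    """First ``k`` of the ranked order; asks for more than exist → all, warned."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if k > len(table.rank_order):
        logger.warning("top_k: k=%d exceeds %d ranked nodes; returning all", k, len(table.rank_order))
    return table.rank_order[:k]
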