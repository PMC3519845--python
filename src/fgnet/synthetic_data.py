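"""Synthetic interactomes, expression tables and annotation sets with known truth.

The generators stand in for inputs that cannot ship with the package: a
commercial curated interactome, two Affymetrix ATH1 expression comparisons
and an ontology annotation release.  Each generator plants recoverable
structure — scale-free hubs, bottleneck connectors between dense clusters,
differential-expression effects that straddle the screening thresholds, and
one enriched annotation term — so every downstream stage can be validated
against ground truth.

All randomness flows from a single :class:`numpy.random.Generator` seeded
with ``cfg.rng_seed``; each public generator creates its stream at entry, so
each call is bit-reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .core_io import (
    AnnotationSet,
    ExpressionRecord,
    InteractionNetwork,
    Node,
    REL_TYPES,
    Relation,
)

__all__ = [
    "SimConfig",
    "ConfigError",
    "simulate_interactome",
    "plant_bottlenecks",
    "simulate_expression",
    "simulate_annotations",
]


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


#: Relation-type sampling weights for synthetic edges.  Binding dominates, as
#: in curated interactomes; the exact mix is not meant to match any database.
REL_TYPE_WEIGHTS: dict[str, float] = {
    "binding": 0.40,
    "regulation": 0.20,
    "direct_regulation": 0.10,
    "expression": 0.10,
    "protein_modification": 0.08,
    "promoter_binding": 0.05,
    "mol_synthesis": 0.03,
    "mol_transport": 0.02,
    "chemical_reaction": 0.02,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults realise the conditions the validation suite assumes: planted
    effects of 2.0 (up) and 0.5 (down) with p ≤ 0.01 against a null band of
    fold changes in [0.8, 1.25] and uniform p-values, two dense 15-node
    clusters joined by one connector, and one fully overlapping enriched term
    among 50 null terms of size 10 on a background of a few hundred proteins.
    """

    n_nodes: int = 500
    attach_m: int = 3
    n_clusters: int = 2
    cluster_size: int = 15
    n_connectors: int = 1
    cluster_p: float = 0.8  # within-cluster edge probability
    de_fraction: float = 0.10
    up_effect: float = 2.0
    down_effect: float = 0.5
    de_p_max: float = 0.01
    n_terms: int = 50
    term_size: int = 10
    planted_term_overlap: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_nodes >= 2, "n_nodes must be ≥ 2"),
            (self.attach_m >= 1, "attach_m must be ≥ 1"),
            (self.attach_m < self.n_nodes, "attach_m must be < n_nodes"),
            (self.n_clusters >= 0, "n_clusters must be ≥ 0"),
            (self.n_connectors >= 0, "n_connectors must be ≥ 0"),
            (0.0 < self.de_fraction < 1.0, "de_fraction must lie in (0, 1)"),
            (self.up_effect > 1.5, "up_effect must exceed the 1.5 screen"),
            (0.0 < self.down_effect < 0.66, "down_effect must lie below the 0.66 screen"),
            (0.0 < self.de_p_max < 0.05, "de_p_max must lie below the 0.05 screen"),
            (self.n_terms >= 1, "n_terms must be ≥ 1"),
            (self.term_size >= 1, "term_size must be ≥ 1"),
            (0.0 < self.planted_term_overlap <= 1.0, "planted_term_overlap must lie in (0, 1]"),
            (0.0 < self.cluster_p <= 1.0, "cluster_p must lie in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)


def _node_id(i: int, width: int) -> str:
    return f"N{i:0{width}d}"


def simulate_interactome(cfg: SimConfig) -> InteractionNetwork:
    """Scale-free interactome via Barabási–Albert preferential attachment.

    The backbone has exactly ``attach_m · (n_nodes − attach_m)`` edges: the
    process starts from ``attach_m`` isolated nodes and attaches each of the
    remaining ``n_nodes − attach_m`` nodes with ``attach_m`` edges.  Relation
    types are drawn from :data:`REL_TYPE_WEIGHTS`; effects are positive,
    negative or unknown with probability 0.4/0.3/0.3.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    backbone = nx.barabasi_albert_graph(cfg.n_nodes, cfg.attach_m, seed=int(rng.integers(2**31)))
    width = len(str(cfg.n_nodes - 1))
    net = InteractionNetwork("synthetic-interactome")
    for i in range(cfg.n_nodes):
        net.add_node(Node(_node_id(i, width)))
    _attach_relations(net, ((u, v) for u, v in sorted(backbone.edges())), rng, width)
    return net


def _attach_relations(net: InteractionNetwork, pairs: Iterable[tuple[int, int]], rng, width: int) -> None:
    types = list(REL_TYPE_WEIGHTS)
    probs = np.array([REL_TYPE_WEIGHTS[t] for t in types])
    probs = probs / probs.sum()
    effects = ("positive", "negative", "unknown")
    for u, v in pairs:
        rel_type = types[int(rng.choice(len(types), p=probs))]
        effect = effects[int(rng.choice(3, p=[0.4, 0.3, 0.3]))]
        net.add_relation(
            Relation(_node_id(u, width), _node_id(v, width), rel_type, effect)
        )


def plant_bottlenecks(cfg: SimConfig) -> tuple[InteractionNetwork, set[str]]:
    """Dense clusters joined *only* through connector nodes.

    Each cluster is a dense Erdős–Rényi subgraph (edge probability
    ``cluster_p``, re-drawn until connected); every connector is wired to a
    couple of nodes in every cluster, and clusters share no direct edges.
    Removing all connectors therefore disconnects the graph — asserted on
    every instance before returning.  Returns the network and the truth set
    of connector ids.
    """
    if cfg.n_clusters < 2:
        raise ConfigError("plant_bottlenecks needs n_clusters ≥ 2")
    if cfg.n_connectors < 1:
        raise ConfigError("plant_bottlenecks needs n_connectors ≥ 1")
    if cfg.cluster_size < 2:
        raise ConfigError("cluster_size must be ≥ 2")
    if cfg.n_clusters * cfg.cluster_size + cfg.n_connectors > cfg.n_nodes:
        raise ConfigError("clusters plus connectors exceed n_nodes")
    rng = np.random.default_rng(cfg.rng_seed)
    n_total = cfg.n_clusters * cfg.cluster_size + cfg.n_connectors
    width = len(str(n_total - 1))

    g = nx.Graph()
    clusters: list[list[int]] = []
    next_id = 0
    for _ in range(cfg.n_clusters):
        members = list(range(next_id, next_id + cfg.cluster_size))
        next_id += cfg.cluster_size
        while True:
            sub = nx.erdos_renyi_graph(cfg.cluster_size, cfg.cluster_p, seed=int(rng.integers(2**31)))
            if nx.is_connected(sub):
                break
        g.add_nodes_from(members)
        g.add_edges_from((members[a], members[b]) for a, b in sub.edges())
        clusters.append(members)
    connectors = list(range(next_id, next_id + cfg.n_connectors))
    anchors_per_cluster = min(2, cfg.cluster_size)
    for c in connectors:
        g.add_node(c)
        for members in clusters:
            anchors = rng.choice(members, size=anchors_per_cluster, replace=False)
            g.add_edges_from((c, int(a)) for a in anchors)

    check = g.copy()
    check.remove_nodes_from(connectors)
    assert not nx.is_connected(check), "connector removal must disconnect the graph"

    net = InteractionNetwork("planted-bottlenecks")
    for i in sorted(g.nodes):
        net.add_node(Node(_node_id(i, width)))
    _attach_relations(net, ((u, v) for u, v in sorted(g.edges())), rng, width)
    truth = {_node_id(c, width) for c in connectors}
    return net, truth


def simulate_expression(
    net: InteractionNetwork, cfg: SimConfig
) -> tuple[list[ExpressionRecord], set[str], set[str]]:
    """Expression table with planted up/down effects over the network's proteins.

    Truth genes receive fold change exactly ``up_effect`` / ``down_effect``
    with p ~ U(0, de_p_max); nulls get fold changes log-uniform in
    [0.8, 1.25] — strictly inside the no-call band — with p ~ U(0, 1), so the
    strict screening thresholds recover the truth sets exactly.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    proteins = sorted(nid for nid, node in net.nodes.items() if node.kind == "protein")
    if cfg.de_fraction * len(proteins) < 2:
        raise ConfigError(
            f"de_fraction {cfg.de_fraction} over {len(proteins)} protein nodes plants "
            f"fewer than 2 DE genes"
        )
    n_de = int(round(cfg.de_fraction * len(proteins)))
    chosen = rng.choice(len(proteins), size=n_de, replace=False)
    de_genes = [proteins[i] for i in sorted(chosen)]
    half = n_de // 2
    truth_up = set(de_genes[:half] if half else de_genes[:1])
    truth_down = set(de_genes[len(truth_up):])
    records: list[ExpressionRecord] = []
    for gene in proteins:
        if gene in truth_up:
            fc = cfg.up_effect
            p = float(rng.uniform(0.0, cfg.de_p_max))
        elif gene in truth_down:
            fc = cfg.down_effect
            p = float(rng.uniform(0.0, cfg.de_p_max))
        else:
            fc = float(np.exp(rng.uniform(np.log(0.8), np.log(1.25))))
            p = float(rng.uniform(0.0, 1.0))
        records.append(ExpressionRecord(gene, fc, p))
    return records, truth_up, truth_down


def simulate_annotations(
    net: InteractionNetwork, cfg: SimConfig, target_genes: set[str]
) -> AnnotationSet:
    """Annotation sets with one planted enriched term.

    The planted term (``TERM_PLANTED``) overlaps ``target_genes`` by fraction
    ``planted_term_overlap`` and is padded to ``term_size`` with non-target
    genes; the remaining ``n_terms`` terms sample genes uniformly from the
    background (all protein nodes).
    """
    if not target_genes:
        raise ConfigError("target_genes must be non-empty")
    rng = np.random.default_rng(cfg.rng_seed)
    background = sorted(nid for nid, node in net.nodes.items() if node.kind == "protein")
    bg_set = set(background)
    if not target_genes <= bg_set:
        raise ConfigError("target_genes must be protein nodes of the network")
    targets = sorted(target_genes)
    n_overlap = max(1, int(round(cfg.planted_term_overlap * len(targets))))
    if n_overlap > len(targets):
        raise ConfigError("planted overlap exceeds target set")
    picked = rng.choice(len(targets), size=n_overlap, replace=False)
    planted = {targets[i] for i in picked}
    non_target = [g for g in background if g not in target_genes]
    pad = max(0, cfg.term_size - len(planted))
    if pad > len(non_target):
        raise ConfigError("term_size cannot be met outside the target set")
    if pad:
        extra = rng.choice(len(non_target), size=pad, replace=False)
        planted |= {non_target[i] for i in extra}
    terms: dict[str, tuple[str, frozenset[str]]] = {
        "TERM_PLANTED": ("planted enriched term", frozenset(planted))
    }
    size = min(cfg.term_size, len(background))
    for t in range(cfg.n_terms):
        idx = rng.choice(len(background), size=size, replace=False)
        terms[f"TERM{t:04d}"] = (f"null term {t}", frozenset(background[i] for i in idx))
    return AnnotationSet(terms, frozenset(background))
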