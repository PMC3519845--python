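"""Shortest-path network construction, DE-anchored subtraction and summaries.

Network construction follows the closest-member principle: for every seed
entity and every biological group (a named container of entities such as a
process, enzyme family or complex), the seed is connected to the *nearest*
members of that group — all members at the minimal distance, along *all*
shortest paths.  Path finding runs on the undirected simple topology, so
directed regulatory relations and undirected physical bindings are walked
alike; relation attributes are preserved on the output.

Subtraction keeps exactly the interactions with at least one differentially
expressed endpoint, yielding the DE-anchored subnetwork whose topology the
hub-ranking stage analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .core_io import DEGeneSet, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSpec",
    "NetworkSummary",
    "shortest_path_network",
    "subtract_network",
    "summarize",
]


@dataclass(frozen=True)
class GroupSpec:
    """A named biological group: container of one or more entities."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")


@dataclass(frozen=True)
class NetworkSummary:
    """Headline statistics of a (subtracted) network."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_degree_int: int  # truncated toward zero, the conventionally reported integer
    n_up: int
    n_down: int
    degree_by_node: dict[str, int] = field(compare=False, default_factory=dict)


def shortest_path_network(
    interactome: InteractionNetwork,
    seeds: set[str],
    groups: list[GroupSpec],
    max_len: int = 4,
) -> InteractionNetwork:
    """Union of all shortest seed→nearest-group-member paths.

    For each seed ``s`` and group ``G``: let ``d*`` be the minimal unweighted
    distance from ``s`` to any member of ``G`` on the undirected topology.
    If ``d* ≤ max_len``, *every* shortest path from ``s`` to *every* member
    at distance ``d*`` is included.  Seeds out of range of a group are logged
    and contribute nothing for it.  The output carries all original relation
    attributes between included node pairs.
    """
    if not groups:
        raise ValueError("at least one group is required")
    unknown = seeds - interactome.node_ids()
    if unknown:
        raise ValueError(f"unknown seed ids: {sorted(unknown)[:5]}")
    if max_len < 1:
        raise ValueError("max_len must be ≥ 1")
    for group in groups:
        missing = group.members - interactome.node_ids()
        if missing:
            raise ValueError(f"group {group.name!r} members absent from interactome: {sorted(missing)[:5]}")

    g = interactome.to_graph()
    keep_nodes: set[str] = set()
    keep_edges: set[frozenset[str]] = set()
    for seed in sorted(seeds):
        dist = nx.single_source_shortest_path_length(g, seed, cutoff=max_len)
        for group in groups:
            reachable = {m: dist[m] for m in group.members if m in dist}
            if not reachable:
                logger.info("seed %s: no member of group %r within %d hops", seed, group.name, max_len)
                continue
            d_star = min(reachable.values())
            keep_nodes.add(seed)
            for member, d in reachable.items():
                if d != d_star:
                    continue
                if d == 0:  # the seed is itself a group member: zero-length path
                    continue
                for path in nx.all_shortest_paths(g, seed, member):
                    keep_nodes.update(path)
                    keep_edges.update(frozenset(e) for e in zip(path, path[1:]))

    out = InteractionNetwork(f"{interactome.name}-sp")
    for nid in sorted(keep_nodes):
        out.add_node(interactome.nodes[nid])
    for rel in interactome.relations:
        if frozenset((rel.source, rel.target)) in keep_edges:
            out.add_relation(rel)
    return out


def subtract_network(net: InteractionNetwork, deset: DEGeneSet) -> InteractionNetwork:
    """Keep only interactions with ≥ 1 differentially expressed endpoint.

    Retained nodes are exactly those incident to a retained relation; their
    ``de_status`` is set from the gene sets.  An empty result is permitted.
    """
    de = deset.all
    keep_rels = [r for r in net.relations if r.source in de or r.target in de]
    keep_nodes = {r.source for r in keep_rels} | {r.target for r in keep_rels}
    out = InteractionNetwork(f"{net.name}-sub")
    for nid in sorted(keep_nodes):
        out.add_node(net.nodes[nid])
    for rel in keep_rels:
        out.add_relation(rel)
    out.set_de_status(deset.up, deset.down)
    if not keep_rels:
        logger.info("subtraction produced an empty network")
    return out


def summarize(net: InteractionNetwork, deset: DEGeneSet | None = None) -> NetworkSummary:
    """Node/edge counts, mean degree (real and truncated) and DE tallies.

    Degree counts distinct neighbours on the undirected simple topology, so
    the mean degree is 2·E/V; the integer report truncates toward zero.
    """
    g = net.to_graph()
    n_nodes, n_edges = g.number_of_nodes(), g.number_of_edges()
    avg = 2.0 * n_edges / n_nodes if n_nodes else 0.0
    de_up = deset.up if deset else set()
    de_down = deset.down if deset else set()
    return NetworkSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        avg_degree=avg,
        avg_degree_int=math.trunc(avg),
        n_up=len(set(g.nodes) & de_up),
        n_down=len(set(g.nodes) & de_down),
        degree_by_node={n: int(d) for n, d in g.degree()},
    )
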