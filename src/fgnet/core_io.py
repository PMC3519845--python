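"""Domain types and file I/O for interaction networks, expression tables and gene sets.

The in-memory model mirrors a curated plant interactome: nodes are typed
molecular entities (proteins, small molecules, functional classes, complexes,
cell processes) and relations are typed, signed and optionally directed
(binding, regulation, expression, ...).  Graph algorithms downstream operate
on the *simple undirected topology*: parallel relations between the same node
pair collapse onto one walkable edge, while every relation record is preserved
for round-tripping.

Supported formats
-----------------
* SIF       — ``node1 relation node2``, whitespace separated.
* edge TSV  — columns ``source  rel_type  effect  directed  target  references``.
* expression TSV — columns ``gene_id  fold_change  p_value``.
* GMT       — ``term<TAB>description<TAB>gene...`` one gene set per line.

Both network dialects accept ``#`` comment lines.  Node attributes (kind,
differential-expression status) cannot be expressed on an edge row, so the
writers emit ``#!node`` directive lines that the readers interpret and other
tools skip as comments; this keeps round trips lossless, including for
isolated nodes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

NODE_KINDS = ("protein", "small_molecule", "functional_class", "complex", "cell_process")

REL_TYPES = (
    "binding",
    "protein_modification",
    "direct_regulation",
    "expression",
    "promoter_binding",
    "mol_synthesis",
    "mol_transport",
    "regulation",
    "chemical_reaction",
    "unknown",
)

EFFECTS = ("positive", "negative", "unknown")

#: Default directedness per relation type when a file does not say (SIF has no
#: directed column).  Binding is physical and symmetric; chemical reactions are
#: walked both ways; everything else carries a source-to-target arrow.
DEFAULT_DIRECTED: dict[str, bool] = {
    "binding": False,
    "chemical_reaction": False,
    "unknown": False,
    "protein_modification": True,
    "direct_regulation": True,
    "expression": True,
    "promoter_binding": True,
    "mol_synthesis": True,
    "mol_transport": True,
    "regulation": True,
}


class NetworkFormatError(ValueError):
    """Malformed or inconsistent network/table input."""


@dataclass(frozen=True)
class Node:
    """A typed entity in the interactome.

    ``de_status`` records whether the entity was called up- or downregulated
    by the expression screen (``"none"`` otherwise).
    """

    id: str
    kind: str = "protein"
    de_status: str = "none"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkFormatError("node id must be non-empty")
        if self.kind not in NODE_KINDS:
            raise NetworkFormatError(f"unknown node kind {self.kind!r} for node {self.id!r}")
        if self.de_status not in ("up", "down", "none"):
            raise NetworkFormatError(f"invalid de_status {self.de_status!r} for node {self.id!r}")


@dataclass(frozen=True)
class Relation:
    """A typed, signed, optionally directed relation between two entities.

    Undirected relations are canonicalized with the lexicographically smaller
    endpoint first so duplicates are detectable regardless of input order.
    """

    source: str
    target: str
    rel_type: str = "unknown"
    effect: str = "unknown"
    directed: bool | None = None
    references: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rel_type not in REL_TYPES:
            raise NetworkFormatError(f"unknown relation type {self.rel_type!r}")
        if self.effect not in EFFECTS:
            raise NetworkFormatError(f"unknown effect {self.effect!r}")
        if self.source == self.target:
            raise NetworkFormatError(f"self-loop on {self.source!r} rejected")
        directed = self.directed
        if directed is None:
            directed = DEFAULT_DIRECTED[self.rel_type]
        # binding is always symmetric; promoter binding / expression always arrows
        if self.rel_type == "binding":
            directed = False
        elif self.rel_type in ("promoter_binding", "expression"):
            directed = True
        object.__setattr__(self, "directed", directed)
        if not directed and self.source > self.target:
            src, tgt = self.target, self.source
            object.__setattr__(self, "source", src)
            object.__setattr__(self, "target", tgt)

    @property
    def key(self) -> tuple[str, str, str]:
        """Canonical identity triple used for duplicate detection."""
        return (self.source, self.target, self.rel_type)


class InteractionNetwork:
    """A validated set of typed nodes plus typed relations.

    Referential integrity is enforced on every mutation: relations may only
    join nodes already present, self-loops are rejected, and the canonical
    ``(source, target, rel_type)`` triple is unique.
    """

    def __init__(self, name: str = "network") -> None:
        self.name = name
        self._nodes: dict[str, Node] = {}
        self._relations: dict[tuple[str, str, str], Relation] = {}

    # -- construction -------------------------------------------------
    def add_node(self, node: Node | str, **kwargs) -> Node:
        if isinstance(node, str):
            node = Node(node, **kwargs)
        existing = self._nodes.get(node.id)
        if existing is not None and existing != node:
            raise NetworkFormatError(f"conflicting redefinition of node {node.id!r}")
        self._nodes[node.id] = node
        return node

    def add_relation(self, rel: Relation, create_nodes: bool = False) -> Relation:
        for endpoint in (rel.source, rel.target):
            if endpoint not in self._nodes:
                if create_nodes:
                    self.add_node(endpoint)
                else:
                    raise NetworkFormatError(f"relation references unknown node {endpoint!r}")
        if rel.key in self._relations:
            raise NetworkFormatError(f"duplicate relation {rel.key}")
        self._relations[rel.key] = rel
        return rel

    def set_de_status(self, up: Iterable[str], down: Iterable[str]) -> None:
        """Re-tag nodes with their differential-expression call."""
        up, down = set(up), set(down)
        for nid, node in list(self._nodes.items()):
            status = "up" if nid in up else "down" if nid in down else "none"
            if node.de_status != status:
                self._nodes[nid] = Node(nid, node.kind, status)

    # -- access -------------------------------------------------------
    @property
    def nodes(self) -> Mapping[str, Node]:
        return self._nodes

    @property
    def relations(self) -> tuple[Relation, ...]:
        return tuple(self._relations.values())

    def node_ids(self) -> set[str]:
        return set(self._nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def relations_between(self, a: str, b: str) -> list[Relation]:
        return [r for r in self._relations.values() if {r.source, r.target} == {a, b}]

    def to_graph(self) -> nx.Graph:
        """The simple undirected topology every graph algorithm runs on.

        Parallel relations collapse onto one edge; direction and effect ride
        along as an edge attribute list.
        """
        g = nx.Graph(name=self.name)
        for node in self._nodes.values():
            g.add_node(node.id, kind=node.kind, de_status=node.de_status)
        for rel in self._relations.values():
            a, b = sorted((rel.source, rel.target))
            if g.has_edge(a, b):
                g[a][b]["relations"].append(rel)
            else:
                g.add_edge(a, b, relations=[rel])
        return g

    def subnetwork(self, node_ids: Iterable[str], name: str | None = None) -> "InteractionNetwork":
        keep = set(node_ids)
        out = InteractionNetwork(name or self.name)
        for nid in sorted(keep):
            out.add_node(self._nodes[nid])
        for rel in self._relations.values():
            if rel.source in keep and rel.target in keep:
                out.add_relation(rel)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._relations == other._relations

    def __repr__(self) -> str:
        return f"InteractionNetwork({self.name!r}, nodes={len(self._nodes)}, relations={len(self._relations)})"


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's measurement: raw fold-change ratio and screening p-value."""

    gene_id: str
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise NetworkFormatError("gene_id must be non-empty")
        if not self.fold_change > 0:
            raise NetworkFormatError(f"{self.gene_id}: fold_change must be > 0, got {self.fold_change}")
        if not 0.0 <= self.p_value <= 1.0:
            raise NetworkFormatError(f"{self.gene_id}: p_value {self.p_value} outside [0, 1]")


@dataclass
class DEGeneSet:
    """Disjoint up/down gene sets with the thresholds that produced them."""

    up: set[str]
    down: set[str]
    thresholds: tuple[float, float, float] = (1.5, 0.66, 0.05)  # (up_fc, down_fc, alpha)

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise NetworkFormatError(f"genes called both up and down: {sorted(overlap)}")

    @property
    def all(self) -> set[str]:
        return self.up | self.down


@dataclass
class AnnotationSet:
    """Flat gene-set annotations (GMT style) plus a background universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise NetworkFormatError(f"term {term_id!r} annotates no genes")
            missing = genes - self.background
            if missing:
                raise NetworkFormatError(
                    f"term {term_id!r} annotates genes outside the background: {sorted(missing)[:5]}"
                )


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

_TSV_HEADER = ["source", "rel_type", "effect", "directed", "target", "references"]


def _parse_node_directive(parts: list[str], lineno: int) -> Node:
    if len(parts) != 4:
        raise NetworkFormatError(f"line {lineno}: malformed #!node directive")
    _, nid, kind, de_status = parts
    return Node(nid, kind, de_status)


def read_network(path: str | Path, dialect: str = "tsv", name: str | None = None) -> InteractionNetwork:
    """Load an :class:`InteractionNetwork` from a SIF or edge-TSV file.

    Unknown relation-type strings map to ``unknown`` with a warning; node
    kinds default to ``protein`` when the file carries no directive for them.
    Malformed rows and duplicate canonical relations raise
    :class:`NetworkFormatError` naming the offending line.
    """
    path = Path(path)
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    net = InteractionNetwork(name or path.stem)
    pending: list[tuple[int, Relation]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#!node"):
                sep = "\t" if dialect == "tsv" else None
                net.add_node(_parse_node_directive(line.split(sep), lineno))
                continue
            if line.startswith("#"):
                continue
            if dialect == "sif":
                parts = line.split()
                if len(parts) != 3:
                    raise NetworkFormatError(f"line {lineno}: expected 'node relation node', got {line!r}")
                src, rel_type, tgt = parts
                rel_type = _coerce_rel_type(rel_type, lineno)
                rel = _make_relation(src, tgt, rel_type, "unknown", None, (), lineno)
            else:
                parts = line.split("\t")
                if lineno == 1 or parts[: len(_TSV_HEADER)] == _TSV_HEADER:
                    if parts[: len(_TSV_HEADER)] != _TSV_HEADER:
                        expected = "\t".join(_TSV_HEADER)
                        raise NetworkFormatError(f"line {lineno}: expected header {expected!r}")
                    continue
                if len(parts) < 5:
                    raise NetworkFormatError(f"line {lineno}: expected ≥5 tab-separated fields, got {line!r}")
                src, rel_type, effect, directed_s, tgt = parts[:5]
                refs = tuple(r for r in (parts[5].split("|") if len(parts) > 5 and parts[5] else ()) if r)
                rel_type = _coerce_rel_type(rel_type, lineno)
                directed = {"true": True, "false": False, "": None}.get(directed_s.strip().lower())
                if directed is None and directed_s.strip().lower() not in ("", "none"):
                    raise NetworkFormatError(f"line {lineno}: directed must be true/false, got {directed_s!r}")
                rel = _make_relation(src, tgt, rel_type, effect, directed, refs, lineno)
            pending.append((lineno, rel))
    for lineno, rel in pending:
        try:
            net.add_relation(rel, create_nodes=True)
        except NetworkFormatError as exc:
            raise NetworkFormatError(f"line {lineno}: {exc}") from exc
    return net


def _coerce_rel_type(rel_type: str, lineno: int) -> str:
    if rel_type not in REL_TYPES:
        logger.warning("line %d: unknown relation type %r mapped to 'unknown'", lineno, rel_type)
        return "unknown"
    return rel_type


def _make_relation(src, tgt, rel_type, effect, directed, refs, lineno) -> Relation:
    try:
        return Relation(src, tgt, rel_type, effect, directed, refs)
    except NetworkFormatError as exc:
        raise NetworkFormatError(f"line {lineno}: {exc}") from exc


def write_network(net: InteractionNetwork, path: str | Path, dialect: str = "tsv") -> None:
    """Write a network so that :func:`read_network` reproduces it exactly.

    Node kinds and DE status travel as ``#!node`` directive lines; the edge
    body matches the dialect's standard layout.
    """
    path = Path(path)
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else " "
    with path.open("w", encoding="utf-8") as fh:
        if dialect == "tsv":
            fh.write("\t".join(_TSV_HEADER) + "\n")
        for nid in sorted(net.nodes):
            node = net.nodes[nid]
            fh.write(sep.join(["#!node", node.id, node.kind, node.de_status]) + "\n")
        for rel in sorted(net.relations, key=lambda r: r.key):
            if dialect == "sif":
                fh.write(f"{rel.source} {rel.rel_type} {rel.target}\n")
            else:
                fh.write(
                    "\t".join(
                        [
                            rel.source,
                            rel.rel_type,
                            rel.effect,
                            "true" if rel.directed else "false",
                            rel.target,
                            "|".join(rel.references),
                        ]
                    )
                    + "\n"
                )


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a ``gene_id  fold_change  p_value`` TSV into records.

    Rows with non-numeric fields are rejected collectively with their line
    numbers; a missing required column is a schema error.
    """
    path = Path(path)
    records: list[ExpressionRecord] = []
    bad: list[str] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        required = {"gene_id", "fold_change", "p_value"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise NetworkFormatError(
                f"{path}: expected columns {sorted(required)}, found {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                fc = float(row["fold_change"])
                p = float(row["p_value"])
            except (TypeError, ValueError):
                bad.append(f"line {lineno}: non-numeric fields {row['fold_change']!r}/{row['p_value']!r}")
                continue
            records.append(ExpressionRecord(row["gene_id"], fc, p))
    if bad:
        raise NetworkFormatError(f"{path}: rejected rows — " + "; ".join(bad))
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tfold_change\tp_value\n")
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.fold_change!r}\t{rec.p_value!r}\n")


def read_annotations(path: str | Path, background: Iterable[str] | None = None) -> AnnotationSet:
    """Read GMT gene sets.  Background defaults to the union of all terms."""
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    union: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise NetworkFormatError(f"line {lineno}: term {parts[0]!r} has zero genes")
            term_id, description = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise NetworkFormatError(f"line {lineno}: term {term_id!r} has zero genes")
            if term_id in terms:
                raise NetworkFormatError(f"line {lineno}: duplicate term id {term_id!r}")
            terms[term_id] = (description, genes)
            union |= genes
    bg = frozenset(background) if background is not None else frozenset(union)
    return AnnotationSet(terms, bg)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for term_id in sorted(ann.terms):
            description, genes = ann.terms[term_id]
            fh.write("\t".join([term_id, description, *sorted(genes)]) + "\n")


def write_scores(table, path: str | Path) -> None:
    """Write a ranked hub-score table as ``rank  node  method  score`` TSV."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("rank\tnode\tmethod\tscore\n")
        for rank, node in enumerate(table.rank_order, start=1):
            fh.write(f"{rank}\t{node}\t{table.method}\t{table.score[node]!r}\n")
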