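"""Threshold screening of expression tables into up/down gene sets.

The screen is deliberately simple and strict: a gene is upregulated when its
fold change exceeds ``up_fc`` (default 1.5) with p below ``alpha`` (default
0.05), downregulated when its fold change is below ``down_fc`` (default
0.66) with p below ``alpha``.  All three comparisons are strict, so records
sitting exactly on a threshold are never selected.  No multiple-testing
correction is applied at this stage — the screen operates on raw p-values.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

from .core_io import DEGeneSet, ExpressionRecord

__all__ = ["select_de_genes", "merge_curated_genes", "deduplicate_records", "InputError"]


class InputError(ValueError):
    """Inconsistent expression input (e.g. conflicting duplicate genes)."""


def deduplicate_records(records: Iterable[ExpressionRecord]) -> list[ExpressionRecord]:
    """Resolve genes measured in several source tables.

    When a gene appears more than once, the record with the smallest p-value
    wins (most-significant evidence); exact duplicate rows collapse silently.
    """
    by_gene: dict[str, ExpressionRecord] = {}
    for rec in records:
        prev = by_gene.get(rec.gene_id)
        if prev is None or rec.p_value < prev.p_value:
            by_gene[rec.gene_id] = rec
    return list(by_gene.values())


def select_de_genes(
    records: Iterable[ExpressionRecord],
    up_fc: float = 1.5,
    down_fc: float = 0.66,
    alpha: float = 0.05,
) -> DEGeneSet:
    """Apply the strict fold-change / p-value screen.

    up   = {g : fc > up_fc  and p < alpha}
    down = {g : fc < down_fc and p < alpha}

    Duplicate gene ids with conflicting measurements are an error; call
    :func:`deduplicate_records` first when merging tables.
    """
    records = list(records)
    if not records:
        raise InputError("no expression records supplied")
    if not (up_fc > down_fc > 0):
        raise InputError(f"need up_fc > down_fc > 0, got {up_fc}, {down_fc}")
    if not (0 < alpha < 1):
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")

    seen: dict[str, ExpressionRecord] = {}
    conflicts: dict[str, list[ExpressionRecord]] = defaultdict(list)
    for rec in records:
        prev = seen.get(rec.gene_id)
        if prev is not None and prev != rec:
            conflicts[rec.gene_id].append(rec)
        seen[rec.gene_id] = rec
    if conflicts:
        raise InputError(
            "duplicate gene_ids with conflicting values: " + ", ".join(sorted(conflicts))
        )

    up = {r.gene_id for r in seen.values() if r.fold_change > up_fc and r.p_value < alpha}
    down = {r.gene_id for r in seen.values() if r.fold_change < down_fc and r.p_value < alpha}
    return DEGeneSet(up=up, down=down, thresholds=(up_fc, down_fc, alpha))


def merge_curated_genes(
    deset: DEGeneSet, extra_up: set[str] = frozenset(), extra_down: set[str] = frozenset()
) -> DEGeneSet:
    """Add externally validated genes (e.g. RT-PCR confirmed) to a screen result.

    Raises if a gene would end up in both directions.
    """
    up = deset.up | set(extra_up)
    down = deset.down | set(extra_down)
    clash = up & down
    if clash:
        raise InputError(f"genes in both directions after merge: {sorted(clash)}")
    return DEGeneSet(up=up, down=down, thresholds=deset.thresholds)
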