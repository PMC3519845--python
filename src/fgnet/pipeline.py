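"""End-to-end pipeline: simulate/load → screen → build → subtract → rank → enrich.

A run is driven by one structured config (YAML mapping) naming either real
input files (``inputs`` block) or a simulation recipe (``simulate`` block) —
never both.  Every stage writes its intermediate to the run directory in the
package's plain-text formats, and the run finishes with a manifest recording
the config snapshot, the seed, SHA-256 digests and row/node/edge counts of
every artifact.  Identical configs and seeds reproduce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .core_io import (
    AnnotationSet,
    DEGeneSet,
    InteractionNetwork,
    read_annotations,
    read_expression_table,
    read_network,
    write_annotations,
    write_expression_table,
    write_network,
    write_scores,
)
from .de_selection import deduplicate_records, select_de_genes
from .enrichment import filter_significant, fisher_enrichment
from .hub_ranking import DSSConfig, bn_scores, degree_scores, dmnc_scores, dss_rank, mnc_scores
from .network_builder import GroupSpec, shortest_path_network, subtract_network, summarize
from .synthetic_data import (
    SimConfig,
    simulate_annotations,
    simulate_expression,
    simulate_interactome,
)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "compare_gene_lists", "load_groups"]

_RANKERS = {
    "degree": lambda net, opts: degree_scores(net),
    "bn": lambda net, opts: bn_scores(net),
    "mnc": lambda net, opts: mnc_scores(net),
    "dmnc": lambda net, opts: dmnc_scores(net, epsilon=opts.get("epsilon", 1.7)),
    "dss": lambda net, opts: dss_rank(
        net, DSSConfig(n_out=opts.get("dss_n", 30), screen_factor=opts.get("screen_factor", 2))
    ),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    rng_seed: int
    config: dict[str, Any]
    digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_groups(path: str | Path) -> list[GroupSpec]:
    """Read ``group_name<TAB>member_id`` rows into group specs."""
    members: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            name, member = line.split("\t")[:2]
            members.setdefault(name, set()).add(member)
    return [GroupSpec(name, frozenset(m)) for name, m in sorted(members.items())]


def groups_from_annotations(ann: AnnotationSet, network_ids: set[str]) -> list[GroupSpec]:
    """Treat each annotation term as a biological group, restricted to the network."""
    groups = []
    for term_id in sorted(ann.terms):
        _, genes = ann.terms[term_id]
        present = frozenset(genes & network_ids)
        if present:
            groups.append(GroupSpec(term_id, present))
    return groups


def compare_gene_lists(
    net: InteractionNetwork, reference: set[str]
) -> tuple[set[str], set[str]]:
    """Partition a reference gene list by membership in the network."""
    if not reference:
        raise ValueError("reference gene list must be non-empty")
    present = reference & net.node_ids()
    return present, reference - present


def run_pipeline(config: dict[str, Any] | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full analysis and return the reproducibility manifest.

    ``config`` is a mapping (or path to a YAML file) with exactly one of a
    ``simulate`` or ``inputs`` block, optional ``select_de``, ``build``,
    ``rank`` and ``enrich`` blocks, and a ``seed``.
    """
    if isinstance(config, (str, Path)):
        with Path(config).open(encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError("config: expected a mapping")
    has_sim, has_inputs = "simulate" in config, "inputs" in config
    if has_sim == has_inputs:
        raise PipelineError("config: exactly one of 'simulate' or 'inputs' is required")

    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "fgnet-run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, rng_seed=seed, config=_jsonable(config))

    # -- stage: obtain inputs -----------------------------------------
    try:
        if has_sim:
            cfg = SimConfig(**{**config["simulate"], "rng_seed": seed})
            interactome = simulate_interactome(cfg)
            records, truth_up, truth_down = simulate_expression(interactome, cfg)
            ann = simulate_annotations(interactome, cfg, truth_up | truth_down)
            write_network(interactome, out / "interactome.tsv", "tsv")
            write_expression_table(records, out / "expression.tsv")
            write_annotations(ann, out / "annotations.gmt")
            truth = {
                "truth_up": sorted(truth_up),
                "truth_down": sorted(truth_down),
                "planted_term": "TERM_PLANTED",
            }
            (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
            groups = None
        else:
            paths = config["inputs"]
            interactome = read_network(paths["network"], paths.get("dialect", "tsv"))
            records = read_expression_table(paths["expression"])
            ann = read_annotations(paths["annotations"]) if "annotations" in paths else None
            groups = load_groups(paths["groups"]) if "groups" in paths else None
    except Exception as exc:
        raise PipelineError(f"stage 'inputs': {exc}") from exc

    # -- stage: DE screening ------------------------------------------
    try:
        de_opts = config.get("select_de", {})
        deset = select_de_genes(
            deduplicate_records(records),
            up_fc=de_opts.get("up_fc", 1.5),
            down_fc=de_opts.get("down_fc", 0.66),
            alpha=de_opts.get("alpha", 0.05),
        )
        with (out / "de_genes.tsv").open("w", encoding="utf-8") as fh:
            fh.write("gene_id\tdirection\n")
            for g in sorted(deset.up):
                fh.write(f"{g}\tup\n")
            for g in sorted(deset.down):
                fh.write(f"{g}\tdown\n")
        manifest.counts["de_up"] = len(deset.up)
        manifest.counts["de_down"] = len(deset.down)
    except Exception as exc:
        raise PipelineError(f"stage 'select-de': {exc}") from exc

    # -- stage: network construction ----------------------------------
    try:
        build_opts = config.get("build", {})
        if groups is None:
            if ann is None:
                raise PipelineError("no groups file and no annotations to derive groups from")
            groups = groups_from_annotations(ann, interactome.node_ids())
        seeds = deset.all & interactome.node_ids()
        skipped = deset.all - seeds
        if skipped:
            logger.info("%d DE genes absent from the interactome", len(skipped))
        if not seeds:
            raise PipelineError("no DE gene is present in the interactome")
        primary = shortest_path_network(
            interactome, seeds, groups, max_len=build_opts.get("max_len", 4)
        )
        write_network(primary, out / "network_primary.tsv", "tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'build': {exc}") from exc

    # -- stage: subtraction + summary ---------------------------------
    try:
        subtracted = subtract_network(primary, deset)
        write_network(subtracted, out / "network_subtracted.tsv", "tsv")
        summary = summarize(subtracted, deset)
        manifest.counts["summary"] = {
            "n_nodes": summary.n_nodes,
            "n_edges": summary.n_edges,
            "avg_degree": summary.avg_degree,
            "avg_degree_int": summary.avg_degree_int,
            "n_up": summary.n_up,
            "n_down": summary.n_down,
        }
        (out / "summary.json").write_text(
            json.dumps(manifest.counts["summary"], indent=2, sort_keys=True)
        )
    except Exception as exc:
        raise PipelineError(f"stage 'subtract': {exc}") from exc

    # -- stage: hub ranking -------------------------------------------
    rank_opts = config.get("rank", {})
    methods = rank_opts.get("methods", ["bn", "dss"])
    target = subtracted if subtracted.relations else primary
    for method in methods:
        if method not in _RANKERS:
            raise PipelineError(f"stage 'rank': unknown method {method!r}")
        try:
            table = _RANKERS[method](target, rank_opts)
            write_scores(table, out / f"rank_{method}.tsv")
            manifest.counts[f"rank_{method}_top"] = table.rank_order[: rank_opts.get("top_k", 30)]
        except Exception as exc:
            raise PipelineError(f"stage 'rank' ({method}): {exc}") from exc

    # -- stage: enrichment --------------------------------------------
    if ann is not None:
        try:
            enrich_opts = config.get("enrich", {})
            study = {n for n in target.node_ids() if target.nodes[n].kind == "protein"}
            results = fisher_enrichment(study, ann, correction=enrich_opts.get("correction", "bh"))
            sig = filter_significant(results, enrich_opts.get("alpha", 0.05))
            with (out / "enrichment.tsv").open("w", encoding="utf-8") as fh:
                fh.write("term_id\tp_adj\tp_raw\tk\tK\tdescription\n")
                for r in results:
                    fh.write(
                        f"{r.term_id}\t{r.p_adj!r}\t{r.p_raw!r}\t{r.k}\t{r.K}\t{r.description}\n"
                    )
            manifest.counts["enriched_terms"] = [r.term_id for r in sig]
        except Exception as exc:
            raise PipelineError(f"stage 'enrich': {exc}") from exc

    for artifact in sorted(out.iterdir()):
        if artifact.name != "manifest.json" and artifact.is_file():
            manifest.digests[artifact.name] = _sha256(artifact)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
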