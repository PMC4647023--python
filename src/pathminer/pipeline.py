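"""End-to-end orchestration: parse -> build -> mine -> permute -> filter -> write.

The pipeline is deterministic: the same inputs, configuration and RNG seed
produce byte-identical output tables, and a ``run_report.json`` records input
digests, the configuration echo and the counts at every stage so a run can be
audited and reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import network_core, path_mining, permutation, string_io

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one full mining run.

    Defaults follow the method's canonical protocol: 1,000 permutation rounds
    and an FDR cutoff of 0.05 (boundary excluded), human species prefix
    ``9606.``, deterministic lexicographic tie-breaking.
    """

    network_path: str
    seed_path: str
    output_dir: str
    species_prefix: str = "9606."
    n_permutations: int = 1000
    fdr_threshold: float = 0.05
    rng_seed: int = 0
    tie_break: str = "lexicographic"
    seed_id_column: str | None = None
    symbol_map_path: str | None = None
    keep_prefix: bool = False
    strict_parse: bool = False
    strict_connectivity: bool = False
    exclude_seeds_from_null: bool = False
    n_workers: int = 1
    write_null_archive: bool = False
    write_graphml: bool = True

    def validate(self) -> None:
        if self.n_permutations <= 0:
            raise ValueError("n_permutations must be a positive integer")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must lie strictly between 0 and 1")
        if self.tie_break not in ("lexicographic", "first-found"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    """Everything a finished run produced, plus the report dictionary."""

    mining: path_mining.MiningResult
    scores: list[permutation.GeneScore]
    candidates: list[permutation.GeneScore]
    written: dict[str, Path] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full mining + permutation pipeline described by ``config``.

    Writes the four result tables, an optional GraphML export and
    ``run_report.json`` under ``config.output_dir``.  On any stage failure the
    partially written outputs of this run are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError("config", str(exc)) from exc

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        # -- parse -----------------------------------------------------------
        try:
            parsed = string_io.parse_string_links(
                config.network_path,
                species_prefix=config.species_prefix,
                strip_prefix=not config.keep_prefix,
                strict=config.strict_parse,
            )
            seeds = string_io.read_seed_set(
                config.seed_path,
                id_column=config.seed_id_column,
                species_prefix=None if config.keep_prefix else config.species_prefix,
            )
            symbol_map = (
                string_io.read_symbol_map(config.symbol_map_path)
                if config.symbol_map_path
                else None
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("parse", str(exc)) from exc

        # -- build -----------------------------------------------------------
        try:
            network = network_core.build_network(parsed.interactions)
        except Exception as exc:
            raise PipelineError("build", str(exc)) from exc

        # -- mine ------------------------------------------------------------
        try:
            mining = path_mining.mine_seed_paths(
                network,
                seeds,
                tie_break=config.tie_break,
                strict_connectivity=config.strict_connectivity,
            )
        except Exception as exc:
            raise PipelineError("mine", str(exc)) from exc

        # -- permute ---------------------------------------------------------
        try:
            perm_config = permutation.PermutationConfig(
                set_size=len(mining.seeds_used),
                n_rounds=config.n_permutations,
                threshold=config.fdr_threshold,
                rng_seed=config.rng_seed,
                universe="non-seed" if config.exclude_seeds_from_null else "all",
            )
            random_sets = permutation.sample_random_sets(
                network, perm_config, seeds=seeds
            )
            archive = (
                str(out_dir / "null_betweenness.tsv.gz")
                if config.write_null_archive
                else None
            )
            scores = permutation.permutation_fdr(
                network,
                mining,
                random_sets,
                tie_break=config.tie_break,
                threshold=config.fdr_threshold,
                n_workers=config.n_workers,
                null_archive=archive,
            )
            if archive:
                written["null_archive"] = Path(archive)
            candidates = permutation.filter_candidates(
                scores, threshold=config.fdr_threshold
            )
        except Exception as exc:
            raise PipelineError("permute", str(exc)) from exc

        # -- write -----------------------------------------------------------
        try:
            # scores sorted the same way the candidate table is
            ordered = sorted(
                scores, key=lambda s: (-s.observed_betweenness, s.gene)
            )
            written.update(
                string_io.write_results(
                    mining.paths,
                    ordered,
                    out_dir,
                    symbol_map=symbol_map,
                    threshold=config.fdr_threshold,
                )
            )
            if config.write_graphml:
                used = _paths_subgraph(network, mining)
                graphml = out_dir / "paths_graph.graphml"
                network_core.export_graphml(used, graphml)
                written["graphml"] = graphml

            report = _build_report(config, parsed, seeds, network, mining, scores, candidates)
            report_path = out_dir / "run_report.json"
            report_path.write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            written["report"] = report_path
        except Exception as exc:
            raise PipelineError("write", str(exc)) from exc
    except PipelineError:
        for p in written.values():
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise

    return RunResult(
        mining=mining,
        scores=candidates_first(scores),
        candidates=candidates,
        written=written,
        report=report,
    )


def candidates_first(scores):
    return sorted(scores, key=lambda s: (-s.observed_betweenness, s.gene))


def _paths_subgraph(network, mining):
    """Subgraph induced by the edges actually used in mined paths."""
    import networkx as nx

    g = nx.Graph()
    for p in mining.paths:
        for u, v, w in p.edges():
            g.add_edge(u, v, weight=w, score=1000 - w)
    return network_core.PPINetwork(g)


def _build_report(config, parsed, seeds, network, mining, scores, candidates) -> dict:
    on_path_seeds = mining.involved_genes & set(seeds.members)
    return {
        "config": asdict(config),
        "inputs": {
            "network_sha256": _sha256(config.network_path),
            "seeds_sha256": _sha256(config.seed_path),
        },
        "counts": {
            "directed_records_parsed": parsed.n_directed_records,
            "undirected_interactions": parsed.n_undirected,
            "malformed_lines": parsed.n_malformed,
            "self_loops_dropped": parsed.n_self_loops,
            "nodes": network.n_nodes,
            "edges": network.n_edges,
            "seeds_input": len(seeds),
            "seeds_mapped": len(mining.seeds_used),
            "seeds_dropped": len(mining.dropped_seeds),
            "seed_pairs_connected": len(mining.paths),
            "seed_pairs_skipped": len(mining.skipped_pairs),
            "involved_ids": len(mining.involved_genes),
            "seeds_on_paths": len(on_path_seeds),
            "shortest_path_genes": len(mining.shortest_path_genes),
            "candidates": len(candidates),
        },
        "dropped_seeds": list(mining.dropped_seeds),
        "candidates": [
            {
                "protein_id": s.gene,
                "betweenness": s.observed_betweenness,
                "permutation_fdr": s.permutation_fdr,
            }
            for s in candidates
        ],
    }


def format_candidate_table(candidates, symbol_map=None) -> str:
    """Pretty candidate table; an FDR of exactly 0 prints as '<1/n_rounds'."""
    symbol_map = symbol_map or {}
    lines = ["row\tprotein_id\tgene_symbol\tbetweenness\tpermutation_fdr"]
    for i, s in enumerate(candidates, start=1):
        lines.append(
            f"{i}\t{s.gene}\t{symbol_map.get(s.gene, '-')}\t"
            f"{s.observed_betweenness}\t{permutation.format_fdr(s)}"
        )
    return "\n".join(lines)
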