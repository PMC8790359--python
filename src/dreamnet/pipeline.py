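"""End-to-end orchestration: ingest → classify → network → report.

A single config object carries every tunable parameter with the standard
defaults (1.5σ residual trimming, α = 0.01 edge significance, 2.56 CI
multiplier for the 99% RR bounds, min-degree-5 core, PageRank damping
0.85), so a default run needs no flags. All artifacts are written
deterministically (sorted rows, sorted JSON keys) so identical configs
yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import network as net
from .ingest import read_mentions, read_reports
from .ranking import (
    ClassificationResult,
    classify_conditions,
    count_mention_frequencies,
    count_report_frequencies,
    rank_conditions,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "PipelineStageError", "run_pipeline", "top_conditions"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the standard analysis choices."""

    waking_path: str
    dreams_path: str
    output_dir: str
    k_sigma: float = 1.5
    alpha: float = 0.01
    ci_multiplier: float = 2.56
    min_core_degree: int = 5
    damping: float = 0.85
    weighted_pagerank: bool = True
    lb_threshold: float | None = 1.0
    top_k: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.k_sigma <= 0 or self.ci_multiplier <= 0:
            raise ValueError("k_sigma and ci_multiplier must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 < self.damping < 1):
            raise ValueError("damping must lie in (0, 1)")
        if self.min_core_degree < 1 or self.top_k < 1:
            raise ValueError("min_core_degree and top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class RunReport:
    """Summary of one end-to-end run (the pipeline's printed result)."""

    corpus_totals: dict[str, dict[str, int]]
    class_counts: dict[str, int]
    provenance_counts: dict[str, int]
    n_nodes_before: int
    n_edges_before: int
    n_nodes_after: int
    n_edges_after: int
    n_singletons_removed: int
    giant_component_nodes: int
    giant_component_edges: int
    n_components: int
    core_nodes: int
    core_edges: int
    class_mean_pagerank: dict[str, float]
    assortativity: float
    top_conditions: dict[str, list[tuple[str, int]]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2, allow_nan=True)


def top_conditions(counts: Mapping[str, int], k: int) -> list[tuple[str, int]]:
    """Top-k conditions by count, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return ordered[:k]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def _write_classification_tsv(
    path: Path,
    result: ClassificationResult,
    counts_w: Mapping[str, int],
    counts_d: Mapping[str, int],
    ranks_w: Mapping[str, float],
    ranks_d: Mapping[str, float],
) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            "condition\tcount_waking\tcount_dreams\trank_waking\trank_dreams\tclass\tprovenance\n"
        )
        for cond in sorted(result.class_of):
            fh.write(
                "\t".join(
                    [
                        cond,
                        str(counts_w.get(cond, 0)),
                        str(counts_d.get(cond, 0)),
                        format(ranks_w[cond], ".10g") if cond in ranks_w else "",
                        format(ranks_d[cond], ".10g") if cond in ranks_d else "",
                        result.class_of[cond],
                        result.provenance[cond],
                    ]
                )
                + "\n"
            )


def _write_iteration_trace(path: Path, result: ClassificationResult) -> None:
    trace = [
        {
            "slope": it.slope,
            "intercept": it.intercept,
            "mu": it.mu,
            "sigma": it.sigma,
            "removed_waking": sorted(it.removed_waking),
            "removed_dreams": sorted(it.removed_dreams),
            "n_remaining": it.n_remaining,
        }
        for it in result.iterations
    ]
    path.write_text(json.dumps(trace, sort_keys=True, indent=2) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute ingest → classify → network → metrics and write all artifacts.

    Artifacts in ``config.output_dir``: ``classification.tsv``,
    ``iterations.json``, ``network.graphml``, ``edges.tsv``,
    ``metrics.json`` and ``run.log``. A stage failure aborts with a
    stage-named error; artifacts written so far are preserved.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("ingest")
    def ingest():
        mentions = read_mentions(config.waking_path, "waking")
        reports = read_reports(config.dreams_path)
        return mentions, reports

    mentions, reports = ingest()

    @_stage("classify")
    def classify():
        counts_w = count_mention_frequencies(mentions)
        counts_d = count_report_frequencies(reports)
        ranks_w = rank_conditions(counts_w)
        ranks_d = rank_conditions(counts_d)
        result = classify_conditions(ranks_w, ranks_d, k_sigma=config.k_sigma)
        _write_classification_tsv(
            out / "classification.tsv", result, counts_w, counts_d, ranks_w, ranks_d
        )
        _write_iteration_trace(out / "iterations.json", result)
        return counts_w, counts_d, result

    counts_w, counts_d, result = classify()

    @_stage("network")
    def network_stage():
        condnet = net.build_condition_network(
            reports,
            classes=result.class_of,
            provenance=result.provenance,
            alpha=config.alpha,
            ci_multiplier=config.ci_multiplier,
            lb_threshold=config.lb_threshold,
            damping=config.damping,
            weighted_pagerank=config.weighted_pagerank,
        )
        g = condnet.graph
        for node, score in condnet.pagerank.items():
            g.nodes[node]["pagerank"] = score
            g.nodes[node]["degree"] = g.degree(node)
        net.write_graphml(g, out / "network.graphml")
        net.write_edge_list_tsv(g, out / "edges.tsv")
        return condnet

    condnet = network_stage()

    @_stage("metrics")
    def metrics_stage():
        giant, sizes = net.giant_component(condnet.graph)
        core = net.extract_core(condnet.graph, config.min_core_degree)
        mean_pr = net.class_mean_pagerank(condnet.pagerank, result.class_of) if condnet.pagerank else {}
        report = RunReport(
            corpus_totals={
                "waking": {
                    "records": len({m.record_id for m in mentions}),
                    "conditions": len(mentions),
                    "unique_conditions": len(counts_w),
                },
                "dreams": {
                    "records": len(reports),
                    "conditions": sum(len(r.conditions) for r in reports),
                    "unique_conditions": len(counts_d),
                },
            },
            class_counts=result.class_counts(),
            provenance_counts=result.provenance_counts(),
            n_nodes_before=condnet.n_nodes_unfiltered,
            n_edges_before=condnet.n_edges_unfiltered,
            n_nodes_after=condnet.graph.number_of_nodes(),
            n_edges_after=condnet.graph.number_of_edges(),
            n_singletons_removed=condnet.n_singletons_removed,
            giant_component_nodes=giant.number_of_nodes(),
            giant_component_edges=giant.number_of_edges(),
            n_components=len(sizes),
            core_nodes=core.number_of_nodes(),
            core_edges=core.number_of_edges(),
            class_mean_pagerank=mean_pr,
            assortativity=condnet.assortativity,
            top_conditions={
                "waking": top_conditions(counts_w, config.top_k),
                "dreams": top_conditions(counts_d, config.top_k),
            },
        )
        (out / "metrics.json").write_text(report.to_json() + "\n", encoding="utf-8")
        params = {f.name: getattr(config, f.name) for f in dataclasses.fields(config)}
        (out / "run.log").write_text(
            json.dumps({"parameters": params, "degenerate_pairs": condnet.degenerate_pairs},
                       sort_keys=True, indent=2) + "\n",
            encoding="utf-8",
        )
        return report

    return metrics_stage()
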