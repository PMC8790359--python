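"""Condition co-occurrence network: edge statistics, filtering and analysis.

Nodes are conditions mentioned in dream reports; two conditions are linked
if they appear together in at least one report, with the edge weighted by
the number of reports in which they co-occur. Because frequent conditions
co-occur often purely by chance, each edge carries the statistic set
standard in comorbidity-network analysis:

* relative risk ``RR = P_ij·N / (P_i·P_j)`` — observed co-occurrence over
  the count expected under independence — with a log-normal confidence
  interval ``RR·exp(±m·σ_ij)`` where
  ``σ_ij = sqrt(1/P_ij + 1/(P_i·P_j) − 1/N − 1/N²)`` and the multiplier
  ``m = 2.56`` gives the 99% bounds;
* the phi coefficient ``φ = (P_ij·N − P_i·P_j) /
  sqrt(P_i·P_j·(N−P_i)·(N−P_j))`` — the Pearson correlation of the two
  presence indicators — with a t-test p-value on ``N−2`` degrees of
  freedom.

An edge is robust when ``φ > 0`` and ``p < α`` and the lower RR bound
exceeds 1; everything else is discarded as indistinguishable from chance.
On the filtered graph the module computes PageRank centrality, per-class
mean PageRank, Newman attribute assortativity over the prevalence classes,
connected components and the min-degree core.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.stats import t as t_dist

from .ingest import ReportConditionSet

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceData",
    "EdgeStats",
    "ConditionNetwork",
    "build_cooccurrence",
    "edge_statistics",
    "compute_edge_statistics",
    "filter_edges",
    "build_graph",
    "remove_singletons",
    "pagerank_centrality",
    "class_mean_pagerank",
    "attribute_assortativity",
    "giant_component",
    "extract_core",
    "build_condition_network",
    "write_graphml",
    "write_edge_list_tsv",
]


@dataclass
class CooccurrenceData:
    """Exact co-occurrence counts from a report collection.

    ``n_reports`` is N, ``marginals[c]`` the number of reports mentioning
    condition c (P_i), ``pair_counts[(i, j)]`` the number mentioning both
    (P_ij, keys are sorted pairs, only ever-co-occurring pairs stored).
    """

    n_reports: int
    marginals: dict[str, int]
    pair_counts: dict[tuple[str, str], int]

    @property
    def nodes(self) -> set[str]:
        return set(self.marginals)


def build_cooccurrence(reports: Iterable[ReportConditionSet]) -> CooccurrenceData:
    """Count per-condition and per-pair report memberships."""
    reports = list(reports)
    if not reports:
        raise ValueError("empty report list")
    marginals: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for rep in reports:
        conds = sorted(rep.conditions)
        for c in conds:
            marginals[c] = marginals.get(c, 0) + 1
        for pair in combinations(conds, 2):
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
    return CooccurrenceData(len(reports), marginals, pair_counts)


@dataclass(frozen=True)
class EdgeStats:
    """Full statistic set for one condition pair."""

    rr: float
    sigma: float
    lb: float
    ub: float
    phi: float
    t: float
    p: float
    weight: int
    degenerate: bool = False


def edge_statistics(
    n_reports: int,
    p_i: int,
    p_j: int,
    p_ij: int,
    ci_multiplier: float = 2.56,
) -> EdgeStats:
    """Compute RR, its CI bounds, φ, t and p for one pair.

    A pair with a ubiquitous endpoint (``P_i = N`` or ``P_j = N``) has an
    undefined φ (zero denominator); it is returned with ``degenerate=True``
    and NaN φ/t/p so the edge filter can exclude and log it.
    """
    n = n_reports
    if n < 3:
        raise ValueError("need at least 3 reports for edge statistics")
    if not (1 <= p_ij <= min(p_i, p_j) <= n):
        raise ValueError(f"invalid counts N={n}, P_i={p_i}, P_j={p_j}, P_ij={p_ij}")
    if p_i + p_j - p_ij > n:
        raise ValueError("counts imply more than N reports")

    rr = p_ij * n / (p_i * p_j)
    sigma = math.sqrt(1 / p_ij + 1 / (p_i * p_j) - 1 / n - 1 / n**2)
    ub = rr * math.exp(ci_multiplier * sigma)
    lb = rr * math.exp(-ci_multiplier * sigma)

    if p_i == n or p_j == n:
        return EdgeStats(rr, sigma, lb, ub, math.nan, math.nan, math.nan, p_ij, True)

    phi = (p_ij * n - p_i * p_j) / math.sqrt(p_i * p_j * (n - p_i) * (n - p_j))
    if abs(phi) >= 1.0:  # perfect association: t diverges, p = 0
        phi = max(-1.0, min(1.0, phi))
        t = math.inf if phi > 0 else -math.inf
        p = 0.0
    else:
        t = phi * math.sqrt(n - 2) / math.sqrt(1 - phi * phi)
        p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return EdgeStats(rr, sigma, lb, ub, phi, t, p, p_ij, False)


def compute_edge_statistics(
    data: CooccurrenceData, ci_multiplier: float = 2.56
) -> dict[tuple[str, str], EdgeStats]:
    """Edge statistics for every co-occurring pair in the counts."""
    return {
        pair: edge_statistics(
            data.n_reports, data.marginals[pair[0]], data.marginals[pair[1]],
            count, ci_multiplier,
        )
        for pair, count in data.pair_counts.items()
    }


def filter_edges(
    edges: Mapping[tuple[str, str], EdgeStats],
    alpha: float = 0.01,
    lb_threshold: float | None = 1.0,
) -> dict[tuple[str, str], EdgeStats]:
    """Keep only edges robust to chance co-occurrence.

    An edge survives iff ``φ > 0 and p < alpha`` and ``LB(RR) >
    lb_threshold``. Setting ``alpha >= 1`` disables the significance
    clause and ``lb_threshold=None`` disables the RR-bound clause (useful
    for a vacuous-filter run). Degenerate edges are dropped and logged.
    """
    kept: dict[tuple[str, str], EdgeStats] = {}
    for pair, stats in edges.items():
        if stats.degenerate:
            logger.info("degenerate edge %s (ubiquitous endpoint) excluded", pair)
            continue
        if alpha < 1.0 and not (stats.phi > 0 and stats.p < alpha):
            continue
        if lb_threshold is not None and not (stats.lb > lb_threshold):
            continue
        kept[pair] = stats
    return kept


# -- graph construction and analysis ---------------------------------------


def build_graph(
    nodes: Iterable[str],
    edges: Mapping[tuple[str, str], EdgeStats],
    classes: Mapping[str, str] | None = None,
    provenance: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Assemble the undirected weighted condition graph with attributes."""
    g = nx.Graph()
    for node in sorted(nodes):
        g.add_node(node)
        if classes is not None and node in classes:
            g.nodes[node]["class"] = classes[node]
        if provenance is not None and node in provenance:
            g.nodes[node]["provenance"] = provenance[node]
    for (u, v), s in sorted(edges.items()):
        g.add_edge(
            u, v, weight=s.weight, rr=s.rr, lb=s.lb, ub=s.ub,
            phi=s.phi, t=s.t, p=s.p,
        )
    return g


def remove_singletons(g: nx.Graph) -> nx.Graph:
    """Drop nodes that co-occur with nothing (degree 0)."""
    keep = [n for n in g.nodes if g.degree(n) > 0]
    return g.subgraph(keep).copy()


def pagerank_centrality(
    g: nx.Graph, damping: float = 0.85, weighted: bool = True, tol: float = 1e-12
) -> dict[str, float]:
    """PageRank on the undirected graph.

    Each undirected edge acts as two directed edges; transition
    probabilities are proportional to edge weight when ``weighted``.
    Isolated nodes receive teleport-only mass; scores sum to 1. The
    convergence tolerance is deliberately tight so scores are stable to
    well below any reported precision.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return nx.pagerank(
        g, alpha=damping, weight="weight" if weighted else None,
        tol=tol, max_iter=1000,
    )


def class_mean_pagerank(
    pagerank: Mapping[str, float], classes: Mapping[str, str]
) -> dict[str, float]:
    """Arithmetic mean PageRank per class; absent classes are omitted."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for node, score in pagerank.items():
        cls = classes[node]
        sums[cls] = sums.get(cls, 0.0) + score
        counts[cls] = counts.get(cls, 0) + 1
    return {cls: sums[cls] / counts[cls] for cls in sums}


def attribute_assortativity(g: nx.Graph, attribute: str = "class") -> float:
    """Newman attribute assortativity over edge endpoints; NaN if undefined.

    Undefined when the graph has no edges or all edge endpoints share a
    single class (the mixing matrix is a single cell and the formula
    divides by zero).
    """
    if g.number_of_edges() == 0:
        return math.nan
    endpoint_classes = {g.nodes[u][attribute] for u, v in g.edges} | {
        g.nodes[v][attribute] for u, v in g.edges
    }
    if len(endpoint_classes) < 2:
        return math.nan
    return float(nx.attribute_assortativity_coefficient(g, attribute))


def giant_component(g: nx.Graph) -> tuple[nx.Graph, list[int]]:
    """Largest connected component plus all component sizes (descending)."""
    if g.number_of_nodes() == 0:
        return g.copy(), []
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    sizes = [len(c) for c in components]
    return g.subgraph(components[0]).copy(), sizes


def extract_core(g: nx.Graph, min_degree: int = 5) -> nx.Graph:
    """Induced subgraph on nodes with degree >= min_degree in the full graph.

    A single-pass degree threshold, deliberately not an iterated k-core:
    the core is defined by connectivity in the full filtered network.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    keep = [n for n in g.nodes if g.degree(n) >= min_degree]
    return g.subgraph(keep).copy()


@dataclass
class ConditionNetwork:
    """Filtered condition graph with derived metrics and audit counts."""

    graph: nx.Graph
    pagerank: dict[str, float]
    assortativity: float
    component_sizes: list[int]
    n_nodes_unfiltered: int
    n_edges_unfiltered: int
    n_singletons_removed: int
    degenerate_pairs: list[tuple[str, str]] = field(default_factory=list)


def build_condition_network(
    reports: Iterable[ReportConditionSet],
    classes: Mapping[str, str] | None = None,
    provenance: Mapping[str, str] | None = None,
    alpha: float = 0.01,
    ci_multiplier: float = 2.56,
    lb_threshold: float | None = 1.0,
    damping: float = 0.85,
    weighted_pagerank: bool = True,
) -> ConditionNetwork:
    """Run the full network stage on a report collection.

    Builds co-occurrence counts, drops singleton conditions (those never
    co-occurring with anything), computes the per-edge statistic set,
    filters non-robust edges, drops nodes isolated by the filtering, and
    computes PageRank, assortativity and component sizes on what remains.
    """
    data = build_cooccurrence(reports)
    stats = compute_edge_statistics(data, ci_multiplier)
    degenerate = sorted(p for p, s in stats.items() if s.degenerate)

    unfiltered = build_graph(data.nodes, stats, classes, provenance)
    connected = remove_singletons(unfiltered)
    n_singletons = unfiltered.number_of_nodes() - connected.number_of_nodes()

    kept = filter_edges(stats, alpha=alpha, lb_threshold=lb_threshold)
    filtered = build_graph(connected.nodes, kept, classes, provenance)
    filtered = remove_singletons(filtered)

    pr = pagerank_centrality(filtered, damping, weighted_pagerank) if filtered else {}
    assort = attribute_assortativity(filtered) if classes is not None and filtered else math.nan
    _, sizes = giant_component(filtered)
    return ConditionNetwork(
        graph=filtered,
        pagerank=pr,
        assortativity=assort,
        component_sizes=sizes,
        n_nodes_unfiltered=connected.number_of_nodes(),
        n_edges_unfiltered=connected.number_of_edges(),
        n_singletons_removed=n_singletons,
        degenerate_pairs=degenerate,
    )


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """Write the graph as GraphML, NaN-safe for edge statistics."""
    out = g.copy()
    for _, _, attrs in out.edges(data=True):
        for key, value in list(attrs.items()):
            if isinstance(value, float) and math.isnan(value):
                attrs[key] = "nan"
    nx.write_graphml(out, str(path))


def write_edge_list_tsv(g: nx.Graph, path: str | Path) -> None:
    """Plain TSV edge list with the full statistic set per edge."""
    cols = ["source", "target", "weight", "rr", "lb", "ub", "phi", "t", "p"]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for u, v in sorted(g.edges):
            a = g.edges[u, v]
            fh.write(
                "\t".join(
                    [u, v, str(a["weight"])]
                    + [format(a[k], ".10g") for k in ("rr", "lb", "ub", "phi", "t", "p")]
                )
                + "\n"
            )
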