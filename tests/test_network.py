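import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from dreamnet.ingest import ReportConditionSet
from dreamnet.network import (
    attribute_assortativity,
    build_cooccurrence,
    build_condition_network,
    build_graph,
    class_mean_pagerank,
    compute_edge_statistics,
    edge_statistics,
    extract_core,
    filter_edges,
    giant_component,
    pagerank_centrality,
    remove_singletons,
    write_graphml,
)


def _reports(*sets):
    return [ReportConditionSet(f"d{i}", frozenset(s)) for i, s in enumerate(sets)]


# -- independent oracles ----------------------------------------------------


def contingency_oracle(n, p_i, p_j, p_ij):
    """RR and phi from an explicitly materialised 2x2 table: phi is the
    Pearson correlation of the two presence indicator vectors, RR the
    observed joint probability over the product of the marginals."""
    a, b, c, d = p_ij, p_i - p_ij, p_j - p_ij, n - p_i - p_j + p_ij
    xi = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    xj = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    rr = (a / n) / ((p_i / n) * (p_j / n))
    with np.errstate(invalid="ignore"):
        phi = np.corrcoef(xi, xj)[0, 1]
    return rr, float(phi)


def power_iteration_pagerank(g, damping=0.85, weighted=True, tol=1e-14):
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, attrs in g.edges(data=True):
        wt = attrs.get("weight", 1.0) if weighted else 1.0
        w[idx[u], idx[v]] = wt
        w[idx[v], idx[u]] = wt
    out = w.sum(axis=1)
    p = np.full(n, 1.0 / n)
    for _ in range(10_000):
        nxt = np.full(n, (1 - damping) / n)
        for i in range(n):
            if out[i] > 0:
                nxt += damping * p[i] * w[i] / out[i]
            else:
                nxt += damping * p[i] / n  # dangling: teleport
        if np.abs(nxt - p).sum() < tol:
            p = nxt
            break
        p = nxt
    return {node: p[idx[node]] for node in nodes}


# -- co-occurrence counting -------------------------------------------------


class TestBuildCooccurrence:
    def test_worked_example(self):
        data = build_cooccurrence(_reports({"a", "b"}, {"a", "b"}, {"a", "c"}))
        assert data.n_reports == 3
        assert data.marginals == {"a": 3, "b": 2, "c": 1}
        assert data.pair_counts == {("a", "b"): 2, ("a", "c"): 1}

    def test_single_condition_report_contributes_no_edge(self):
        data = build_cooccurrence(_reports({"a"}))
        assert data.marginals == {"a": 1}
        assert data.pair_counts == {}

    def test_disjoint_reports_no_edges(self):
        data = build_cooccurrence(_reports({"a"}, {"b"}))
        assert data.pair_counts == {}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_cooccurrence([])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vocab = [f"c{i}" for i in range(12)]
        reports = _reports(
            *(
                set(rng.choice(vocab, size=rng.integers(1, 5), replace=False))
                for _ in range(40)
            )
        )
        data = build_cooccurrence(reports)
        for u, v in combinations(sorted({c for r in reports for c in r.conditions}), 2):
            expected = sum(1 for r in reports if u in r.conditions and v in r.conditions)
            assert data.pair_counts.get((u, v), 0) == expected


# -- edge statistics --------------------------------------------------------


class TestEdgeStatistics:
    def test_independence_is_exact(self):
        s = edge_statistics(10, 4, 5, 2)
        assert s.rr == 1.0
        assert s.phi == 0.0

    def test_perfect_association(self):
        s = edge_statistics(10, 5, 5, 5)
        assert s.phi == 1.0
        assert s.p == 0.0

    def test_worked_example_against_oracle(self):
        s = edge_statistics(10, 4, 5, 3)
        rr, phi = contingency_oracle(10, 4, 5, 3)
        assert s.rr == pytest.approx(1.5)
        assert s.rr == pytest.approx(rr, abs=1e-12)
        assert s.phi == pytest.approx(phi, abs=1e-12)
        sigma = math.sqrt(1 / 3 + 1 / 20 - 1 / 10 - 1 / 100)
        assert s.sigma == pytest.approx(sigma)
        assert s.ub == pytest.approx(1.5 * math.exp(2.56 * sigma))
        assert s.lb == pytest.approx(1.5 * math.exp(-2.56 * sigma))
        t = phi * math.sqrt(8) / math.sqrt(1 - phi**2)
        assert s.t == pytest.approx(t)
        from scipy.stats import t as t_dist

        assert s.p == pytest.approx(2 * t_dist.sf(abs(t), 8))

    def test_ci_bounds_bracket_rr(self):
        s = edge_statistics(50, 10, 12, 6)
        assert s.lb <= s.rr <= s.ub

    def test_ubiquitous_condition_is_degenerate(self):
        s = edge_statistics(10, 10, 5, 5)
        assert s.degenerate
        assert math.isnan(s.phi)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            edge_statistics(10, 4, 5, 0)
        with pytest.raises(ValueError):
            edge_statistics(10, 4, 5, 5)
        with pytest.raises(ValueError):
            edge_statistics(5, 4, 4, 1)  # implies 7 reports

    @pytest.mark.parametrize("seed", range(20))
    def test_rr_phi_sign_equivalence(self, seed):
        """rr > 1, phi > 0 and P_ij*N > P_i*P_j are the same event."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        p_i = int(rng.integers(1, n))
        p_j = int(rng.integers(1, n))
        lo = max(1, p_i + p_j - n)
        p_ij = int(rng.integers(lo, min(p_i, p_j) + 1))
        s = edge_statistics(n, p_i, p_j, p_ij)
        assert (s.rr > 1) == (s.phi > 0) == (p_ij * n > p_i * p_j)


class TestFilterEdges:
    def test_independence_dropped(self):
        stats = {("a", "b"): edge_statistics(10, 4, 5, 2)}
        assert filter_edges(stats) == {}

    def test_strong_association_kept(self):
        stats = {("a", "b"): edge_statistics(1000, 40, 40, 40)}
        assert set(filter_edges(stats)) == {("a", "b")}

    def test_degenerate_dropped(self):
        stats = {("a", "b"): edge_statistics(10, 10, 5, 5)}
        assert filter_edges(stats) == {}

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        stats = {}
        for k in range(200):
            n = 100
            p_i = int(rng.integers(1, 60))
            p_j = int(rng.integers(1, 60))
            p_ij = int(rng.integers(max(1, p_i + p_j - n), min(p_i, p_j) + 1))
            stats[(f"a{k}", f"b{k}")] = edge_statistics(n, p_i, p_j, p_ij)
        previous = set()
        for alpha in (0.001, 0.01, 0.05, 0.2, 0.99):
            kept = set(filter_edges(stats, alpha=alpha))
            assert previous <= kept
            previous = kept

    def test_vacuous_filter_keeps_everything(self):
        stats = {
            ("a", "b"): edge_statistics(10, 4, 5, 2),
            ("a", "c"): edge_statistics(10, 4, 5, 1),
        }
        assert filter_edges(stats, alpha=1.0, lb_threshold=None) == stats


# -- graph analysis ---------------------------------------------------------


class TestPageRank:
    def test_two_nodes_one_edge(self):
        g = nx.Graph([("a", "b")])
        pr = pagerank_centrality(g)
        assert pr["a"] == pytest.approx(0.5)
        assert pr["b"] == pytest.approx(0.5)

    def test_regular_graph_uniform(self):
        g = nx.cycle_graph(8)
        pr = pagerank_centrality(g)
        for score in pr.values():
            assert score == pytest.approx(1 / 8, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_power_iteration_oracle(self, seed):
        g = nx.gnm_random_graph(60, 150, seed=seed)
        rng = np.random.default_rng(seed)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = int(rng.integers(1, 10))
        pr = pagerank_centrality(g, damping=0.85)
        oracle = power_iteration_pagerank(g, damping=0.85)
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-9)
        for node in g.nodes:
            assert pr[node] == pytest.approx(oracle[node], abs=1e-8)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            pagerank_centrality(nx.Graph())


class TestClassMeanPagerank:
    def test_single_class(self):
        g = nx.path_graph(4)
        pr = pagerank_centrality(g)
        means = class_mean_pagerank(pr, {n: "x" for n in g.nodes})
        assert means["x"] == pytest.approx(1 / 4)

    def test_two_singleton_classes(self):
        pr = pagerank_centrality(nx.Graph([("a", "b")]))
        means = class_mean_pagerank(pr, {"a": "x", "b": "y"})
        assert means == {"x": pytest.approx(0.5), "y": pytest.approx(0.5)}

    def test_absent_class_omitted(self):
        pr = {"a": 1.0}
        assert "y" not in class_mean_pagerank(pr, {"a": "x"})

    def test_core_periphery_ordering(self):
        """Hub nodes wired to many periphery nodes accumulate more
        PageRank per node than the periphery class."""
        g = nx.Graph()
        classes = {}
        for h in range(3):
            classes[f"hub{h}"] = "EQUAL"
        for i in range(30):
            hub = f"hub{i % 3}"
            g.add_edge(hub, f"leaf{i}")
            classes[f"leaf{i}"] = "TYPICAL_DREAM"
        g.add_edges_from([("hub0", "hub1"), ("hub1", "hub2")])
        means = class_mean_pagerank(pagerank_centrality(g), classes)
        assert means["EQUAL"] > means["TYPICAL_DREAM"]


def mixing_matrix_assortativity(g, classes):
    """Newman's coefficient from a hand-built edge mixing matrix:
    r = (tr(e) - sum_i a_i b_i) / (1 - sum_i a_i b_i)."""
    labels = sorted(set(classes.values()))
    k = len(labels)
    idx = {c: i for i, c in enumerate(labels)}
    e = np.zeros((k, k))
    for u, v in g.edges:
        i, j = idx[classes[u]], idx[classes[v]]
        e[i, j] += 1
        e[j, i] += 1
    e /= e.sum()
    a = e.sum(axis=1)
    return (np.trace(e) - a @ a) / (1 - a @ a)


class TestAssortativity:
    def test_two_same_class_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        for n in g.nodes:
            g.nodes[n]["class"] = "x" if n < 4 else "y"
        assert attribute_assortativity(g) == pytest.approx(1.0)

    def test_complete_bipartite_matches_mixing_matrix(self):
        g = nx.complete_bipartite_graph(3, 5)
        classes = {n: ("x" if n < 3 else "y") for n in g.nodes}
        for n, c in classes.items():
            g.nodes[n]["class"] = c
        assert attribute_assortativity(g) == pytest.approx(
            mixing_matrix_assortativity(g, classes)
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_mixing_matrix_on_random_graphs(self, seed):
        g = nx.gnm_random_graph(30, 80, seed=seed)
        rng = np.random.default_rng(seed)
        classes = {n: f"k{rng.integers(3)}" for n in g.nodes}
        for n, c in classes.items():
            g.nodes[n]["class"] = c
        value = attribute_assortativity(g)
        assert -1 <= value <= 1
        assert value == pytest.approx(mixing_matrix_assortativity(g, classes))

    def test_single_class_undefined(self):
        g = nx.Graph([("a", "b")])
        g.nodes["a"]["class"] = g.nodes["b"]["class"] = "x"
        assert math.isnan(attribute_assortativity(g))

    def test_no_edges_undefined(self):
        g = nx.Graph()
        g.add_node("a", **{"class": "x"})
        assert math.isnan(attribute_assortativity(g))


def union_find_components(g):
    parent = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in g.edges:
        parent[find(u)] = find(v)
    comps = {}
    for n in g.nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted((len(c) for c in comps.values()), reverse=True)


class TestComponentsAndCore:
    def test_path_graph_is_its_own_giant_component(self):
        g = nx.path_graph(5)
        giant, sizes = giant_component(g)
        assert giant.number_of_nodes() == 5
        assert sizes == [5]

    def test_two_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        giant, sizes = giant_component(g)
        assert giant.number_of_nodes() == 3
        assert sizes == [3, 3]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_union_find_oracle(self, seed):
        g = nx.gnm_random_graph(50, 40, seed=seed)
        giant, sizes = giant_component(g)
        oracle = union_find_components(g)
        assert sizes == oracle
        assert giant.number_of_nodes() == oracle[0]

    def test_remove_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        g.add_edge("a", "b")
        assert set(remove_singletons(g).nodes) == {"a", "b"}

    def test_star_core_is_hub_only(self):
        g = nx.star_graph(6)  # hub 0, six leaves
        core = extract_core(g, min_degree=5)
        assert set(core.nodes) == {0}
        assert core.number_of_edges() == 0

    def test_complete_graph_core_unchanged(self):
        g = nx.complete_graph(6)
        core = extract_core(g, min_degree=5)
        assert core.number_of_nodes() == 6
        assert core.number_of_edges() == 15

    @pytest.mark.parametrize("seed", range(3))
    def test_core_matches_degree_filter_oracle(self, seed):
        g = nx.gnm_random_graph(40, 120, seed=seed)
        core = extract_core(g, min_degree=5)
        expected = {n for n in g.nodes if g.degree(n) >= 5}
        assert set(core.nodes) == expected


class TestEndToEndNetwork:
    def test_cluster_recovery(self, cluster_corpora):
        """With strong within-cluster co-occurrence, surviving edges
        concentrate inside planted clusters."""
        _, reports, truth = cluster_corpora
        result = build_condition_network(reports)
        within = sum(
            1
            for u, v in result.graph.edges
            if truth.cluster_of[u] == truth.cluster_of[v]
        )
        assert result.graph.number_of_edges() > 50
        assert within / result.graph.number_of_edges() > 0.9

    def test_counts_and_audit_fields(self, small_corpora):
        _, reports, _ = small_corpora
        result = build_condition_network(reports)
        assert result.graph.number_of_nodes() <= result.n_nodes_unfiltered
        assert result.graph.number_of_edges() <= result.n_edges_unfiltered
        assert sum(result.pagerank.values()) == pytest.approx(1.0, abs=1e-9)
        assert result.component_sizes == sorted(result.component_sizes, reverse=True)

    def test_graphml_round_trip(self, tmp_path, small_corpora):
        _, reports, _ = small_corpora
        result = build_condition_network(reports)
        path = tmp_path / "net.graphml"
        write_graphml(result.graph, path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == result.graph.number_of_nodes()
        assert back.number_of_edges() == result.graph.number_of_edges()
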