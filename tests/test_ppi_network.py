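"""Graph construction, centrality suite, network statistics, prioritization."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hallmarkmap.ppi_network import (
    CentralityRecord,
    PPIEdge,
    attribute_circle_order,
    betweenness,
    build_graph,
    centrality_table,
    degree,
    degree_distribution_fit,
    network_stats,
    prioritize_targets,
    read_edges,
)


def random_graph(rng: np.random.Generator, n: int, p: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}")
    return g


class TestBuildGraph:
    def test_threshold_filters_edges(self):
        edges = [PPIEdge("a", "b", 0.95), PPIEdge("b", "c", 0.80), PPIEdge("c", "d", 0.65)]
        g = build_graph(["a", "b", "c", "d"], edges, 0.9)
        assert g.number_of_edges() == 1 and g.has_edge("a", "b")
        assert g.number_of_nodes() == 4  # isolated nodes retained

    def test_threshold_zero_keeps_all(self):
        edges = [PPIEdge("a", "b", 0.1), PPIEdge("b", "c", 0.5)]
        assert build_graph(["a", "b", "c"], edges, 0.0).number_of_edges() == 2

    def test_self_loop_rejected_at_edge_level(self):
        with pytest.raises(ValueError):
            PPIEdge("a", "a", 0.5)

    def test_duplicate_pairs_collapse_to_best_score(self):
        edges = [PPIEdge("a", "b", 0.4), PPIEdge("b", "a", 0.95)]
        g = build_graph(["a", "b"], edges, 0.9)
        assert g.number_of_edges() == 1

    def test_string_dialects_parse_identically(self, tmp_path):
        rows = [("A", "B", 0.913), ("B", "C", 0.457), ("A", "C", 0.999)]
        f_int = tmp_path / "int.tsv"
        f_int.write_text(
            "protein1\tprotein2\tcombined_score\n"
            + "\n".join(f"{a}\t{b}\t{int(round(s * 1000))}" for a, b, s in rows)
            + "\n"
        )
        f_float = tmp_path / "float.tsv"
        f_float.write_text(
            "a\tb\tscore\n" + "\n".join(f"{a}\t{b}\t{s}" for a, b, s in rows) + "\n"
        )
        e1, e2 = read_edges(f_int), read_edges(f_float)
        assert [(e.a, e.b) for e in e1] == [(e.a, e.b) for e in e2]
        assert all(abs(x.score - y.score) < 1e-9 for x, y in zip(e1, e2))

    def test_malformed_rows_rejected_not_fatal(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("a\tb\tscore\nA\tB\t0.95\nC\tC\t0.9\nD\tE\tnot_a_number\n")
        edges = read_edges(f)
        assert [(e.a, e.b) for e in edges] == [("A", "B")]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        nodes = [f"n{i}" for i in range(40)]
        edges = [
            PPIEdge(nodes[i], nodes[j], float(rng.random()))
            for i in range(40)
            for j in range(i + 1, 40)
            if rng.random() < 0.2
        ]
        prev = None
        for thr in (0.7, 0.9, 0.995):
            g = build_graph(nodes, edges, thr)
            if prev is not None:
                assert g.number_of_edges() <= prev.number_of_edges()
                assert all(g.degree(v) <= prev.degree(v) for v in nodes)
                assert (
                    network_stats(g).density <= network_stats(prev).density + 1e-12
                )
            prev = g


class TestDegree:
    def test_complete_graph(self):
        assert set(degree(nx.complete_graph(4)).values()) == {3}

    def test_star(self):
        d = degree(nx.star_graph(5))
        assert d[0] == 5 and all(d[i] == 1 for i in range(1, 6))

    def test_matches_adjacency_row_sums(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            g = random_graph(rng, 10, 0.3)
            a = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
            sums = a.sum(axis=1)
            d = degree(g)
            for i, v in enumerate(sorted(g.nodes)):
                assert d[v] == sums[i]


class TestBetweenness:
    def test_path_p3(self):
        g = nx.path_graph(["A", "B", "C"])
        b = betweenness(g)
        assert b == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center(self):
        g = nx.star_graph(6)
        b = betweenness(g)
        assert b[0] == pytest.approx(1.0)
        assert all(b[i] == 0.0 for i in range(1, 7))

    def test_small_graphs_all_zero(self):
        assert betweenness(nx.path_graph(2)) == {0: 0.0, 1: 0.0}

    def test_isolated_nodes_count_in_normalization(self):
        # B lies on the single A-C geodesic; with two extra isolated nodes the
        # scale 2/((n-1)(n-2)) uses n=5, so B gets 1/( (4*3)/2 ) = 1/6
        g = nx.path_graph(["A", "B", "C"])
        g.add_nodes_from(["D", "E"])
        assert betweenness(g)["B"] == pytest.approx(1.0 / 6.0)

    def test_matches_networkx_on_random_graphs(self):
        """Cross-check of the in-package Brandes accumulation against the
        independent reference implementation."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            g = random_graph(rng, int(rng.integers(3, 25)), float(rng.uniform(0.05, 0.5)))
            mine = betweenness(g)
            ref = nx.betweenness_centrality(g, normalized=True)
            for v in g.nodes:
                assert mine[v] == pytest.approx(ref[v], abs=1e-12)

    def test_tree_leaves_are_zero(self):
        rng = np.random.default_rng(3)
        g = nx.random_labeled_tree(20, seed=4)
        b = betweenness(g)
        for v in g.nodes:
            if g.degree(v) == 1:
                assert b[v] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_handshake_lemma_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, int(rng.integers(2, 15)), float(rng.uniform(0, 0.6)))
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()
        for v, b in betweenness(g).items():
            assert -1e-12 <= b <= 1.0 + 1e-12
            if g.degree(v) <= 1:
                assert b == 0.0


class TestNetworkStats:
    def test_complete_graph_closed_form(self):
        s = network_stats(nx.complete_graph(4))
        assert s.density == 1.0
        assert s.char_path_length == 1.0
        assert s.diameter == 1 and s.radius == 1
        assert s.mean_clustering == 1.0
        assert s.avg_neighbors == pytest.approx(3.0)

    def test_two_disjoint_edges(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        s = network_stats(g)
        assert s.avg_neighbors == 1.0
        assert s.diameter == 1  # largest component
        assert s.char_path_length == 1.0  # connected pairs only

    def test_edgeless_graph_reports_undefined_markers(self):
        g = nx.empty_graph(5)
        s = network_stats(g)
        assert s.char_path_length is None and s.diameter is None and s.radius is None
        assert s.density == 0.0

    def test_degree_ge_1_scope_drops_isolates(self):
        g = nx.path_graph(["a", "b", "c"])
        g.add_nodes_from(["x", "y"])
        s_all = network_stats(g, "all")
        s_conn = network_stats(g, "degree_ge_1")
        assert s_all.n_nodes == 5 and s_conn.n_nodes == 3
        assert s_conn.node_scope == "degree_ge_1"
        assert s_conn.density > s_all.density

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            g = random_graph(rng, 30, 0.12)
            s = network_stats(g)
            # independent all-pairs BFS oracle
            dists = dict(nx.all_pairs_shortest_path_length(g))
            finite = [d for u in dists for v, d in dists[u].items() if d > 0]
            if finite:
                assert s.char_path_length == pytest.approx(sum(finite) / len(finite))
            comp = max(nx.connected_components(g), key=len)
            if g.number_of_edges():
                ecc = {
                    u: max(dists[u][v] for v in comp)
                    for u in comp
                }
                assert s.diameter == max(ecc.values())
                assert s.radius == min(ecc.values())
            n, m = g.number_of_nodes(), g.number_of_edges()
            assert s.density == pytest.approx(2 * m / (n * (n - 1)))


class TestDegreeDistribution:
    def test_regular_graph_fit_undefined(self):
        with pytest.raises(ValueError):
            degree_distribution_fit(nx.complete_graph(6))

    def test_preferential_attachment_exponent_plausible(self):
        g = nx.barabasi_albert_graph(2000, 2, seed=11)
        hist, exponent, r2 = degree_distribution_fit(g)
        assert 2.0 <= exponent <= 4.0
        assert sum(hist.values()) == 2000

    def test_histogram_conserves_node_count(self):
        g = nx.star_graph(9)
        hist, _, _ = degree_distribution_fit(nx.barabasi_albert_graph(100, 1, seed=3))
        assert sum(hist.values()) == 100


class TestPrioritization:
    def test_star_center_target(self):
        g = nx.star_graph([f"n{i}" for i in range(7)])
        recs = centrality_table(g)
        report = prioritize_targets(recs, {"n0"})
        assert report["targets_upper_third"] == ["n0"]
        assert report["rank_by_degree"][0] == "n0"
        assert report["rank_by_betweenness"][0] == "n0"

    def test_isolated_targets(self):
        g = nx.path_graph(["a", "b", "c"])
        g.add_nodes_from(["t1", "t2"])
        report = prioritize_targets(centrality_table(g), {"t1", "t2"})
        assert report["n_targets_degree_ge_1"] == 0
        assert report["targets_upper_third"] == []

    def test_candidate_novel_targets_flagged(self):
        g = nx.star_graph([f"n{i}" for i in range(10)])
        report = prioritize_targets(centrality_table(g), {"n1"}, degree_cutoff=6)
        assert report["candidate_novel_targets"] == ["n0"]

    def test_stray_target_rejected(self):
        g = nx.path_graph(["a", "b"])
        with pytest.raises(ValueError):
            prioritize_targets(centrality_table(g), {"zzz"})

    def test_planted_hub_recovery_from_ground_truth(self):
        """Hubs planted by the generator land in the top-degree ranks."""
        from hallmarkmap.synthetic_data import GroundTruth, SimConfig, gen_ppi

        genes = [f"G{i:04d}" for i in range(200)]
        cfg = SimConfig(seed=77)
        truth = GroundTruth()
        df = gen_ppi(cfg, genes, truth)
        g = nx.Graph()
        g.add_nodes_from(genes)
        g.add_edges_from(zip(df.protein1, df.protein2))
        top10 = [v for v, _ in sorted(g.degree, key=lambda kv: (-kv[1], kv[0]))[:10]]
        assert len(set(top10) & set(truth.planted_hubs)) >= 4


class TestCircleOrder:
    def test_descending_order(self):
        assert attribute_circle_order({"A": 3, "B": 1, "C": 2}) == ["A", "C", "B"]

    def test_ties_break_lexicographically(self):
        assert attribute_circle_order({"b": 1.0, "a": 1.0, "c": 1.0}) == ["a", "b", "c"]

    def test_matches_reference_sort(self):
        rng = np.random.default_rng(5)
        values = {f"n{i}": float(rng.integers(0, 5)) for i in range(50)}
        expected = sorted(values, key=lambda v: (-values[v], v))
        assert attribute_circle_order(values) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            attribute_circle_order({"a": math.nan})
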