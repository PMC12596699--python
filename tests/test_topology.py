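import math

import networkx as nx
import numpy as np
import pytest

from tecnet import (
    centralities,
    clustering_coefficients,
    path_length_distribution,
    rich_club_curve,
)

from conftest import random_weighted_graph
import _oracles as oracle


def _clustering_of(table, gene):
    return float(table.set_index("gene").loc[gene, "clustering"])


class TestClustering:
    def test_triangle_vertex_is_one_star_center_zero(self):
        tri = nx.complete_graph(3)
        assert _clustering_of(clustering_coefficients(tri), "0") == 1.0
        star = nx.star_graph(5)
        assert _clustering_of(clustering_coefficients(star), "0") == 0.0

    def test_weighted_triangle_hand_computed(self):
        # normalized weights 1.0, 1.0, 0.125; the vertex on both unit
        # edges scores (1 * 1 * 0.125)^(1/3) = 0.5
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.8)
        g.add_edge("a", "c", weight=0.8)
        g.add_edge("b", "c", weight=0.1)
        tab = clustering_coefficients(g, weighted=True)
        assert _clustering_of(tab, "a") == pytest.approx(0.5)

    def test_degree_below_two_scores_zero(self):
        g = nx.path_graph(2)
        tab = clustering_coefficients(g)
        assert set(tab["clustering"]) == {0.0}

    def test_equal_weights_reduce_to_unweighted(self, small_weighted_graph):
        g = small_weighted_graph.copy()
        for _, _, d in g.edges(data=True):
            d["weight"] = 0.37
        unw = clustering_coefficients(g, weighted=False).set_index("gene")
        wtd = clustering_coefficients(g, weighted=True).set_index("gene")
        assert np.allclose(unw["clustering"], wtd["clustering"])

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_bruteforce_oracle(self, weighted):
        for seed in range(3):
            g = random_weighted_graph(18, 0.3, seed)
            tab = clustering_coefficients(g, weighted=weighted).set_index("gene")
            fn = oracle.clustering_weighted if weighted else oracle.clustering_unweighted
            for u in g:
                assert tab.loc[u, "clustering"] == pytest.approx(fn(g, u))

    def test_weighted_mode_requires_weights(self):
        with pytest.raises(ValueError):
            clustering_coefficients(nx.path_graph(4), weighted=True)


class TestRichClub:
    def test_complete_graph_phi_is_one(self):
        curve = rich_club_curve(nx.complete_graph(5))
        assert curve.phi(1) == pytest.approx(1.0)

    def test_path_of_four_interior_nodes(self):
        curve = rich_club_curve(nx.path_graph(4))
        # degree > 1: the two interior nodes, joined by one edge
        assert curve.phi(1) == pytest.approx(1.0)

    def test_single_rich_node_flagged_undefined(self):
        g = nx.star_graph(4)  # only the hub has degree > 1
        curve = rich_club_curve(g)
        assert math.isnan(curve.phi(1))

    def test_matches_bruteforce_filter_and_count(self):
        for seed in range(4):
            g = random_weighted_graph(30, 0.2, seed)
            if g.number_of_edges() == 0:
                continue
            curve = rich_club_curve(g)
            for _, row in curve.table.iterrows():
                expect = oracle.rich_club_phi(g, int(row["k"]))
                if math.isnan(expect):
                    assert math.isnan(row["phi"])
                else:
                    assert row["phi"] == pytest.approx(expect)

    def test_null_normalization_columns_present(self, small_weighted_graph):
        curve = rich_club_curve(small_weighted_graph, n_null=10, seed=0)
        assert {"phi_null_mean", "normalized_ratio"} <= set(curve.table.columns)


class TestPathLengths:
    def test_complete_graph_all_distance_one(self):
        d = path_length_distribution(nx.complete_graph(4))
        assert d.histogram == {1: 6}
        assert d.mean == 1.0

    def test_path_graph_enumeration(self):
        d = path_length_distribution(nx.path_graph(5))
        assert d.histogram == {1: 4, 2: 3, 3: 2, 4: 1}
        assert d.mean == 2.0

    def test_star_mean_closed_form(self):
        n = 9
        d = path_length_distribution(nx.star_graph(n - 1))  # n nodes total
        pairs = n * (n - 1) // 2
        expect = (2 * math.comb(n - 1, 2) + (n - 1)) / pairs
        assert d.mean == pytest.approx(expect)
        assert d.n_pairs == pairs

    def test_restricted_to_largest_component(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.path_graph(3))
        d = path_length_distribution(g)
        assert d.n_component == 5
        assert d.n_pairs == 10


class TestCentralities:
    def test_strength_is_sum_of_incident_weights(self):
        g = nx.Graph()
        g.add_edge("u", "v", weight=0.8)
        g.add_edge("u", "w", weight=0.9)
        tab = centralities(g).set_index("gene")
        assert tab.loc["u", "strength"] == pytest.approx(1.7)

    def test_star_center_betweenness_one_leaves_zero(self):
        tab = centralities(nx.star_graph(6)).set_index("gene")
        assert tab.loc["0", "betweenness"] == pytest.approx(1.0)
        assert tab.loc["1", "betweenness"] == pytest.approx(0.0)

    def test_path_endpoint_closeness(self):
        tab = centralities(nx.path_graph(3)).set_index("gene")
        assert tab.loc["0", "closeness"] == pytest.approx(2 / 3)

    def test_unknown_transform_rejected(self, small_weighted_graph):
        with pytest.raises(ValueError):
            centralities(small_weighted_graph, distance_transform="square")

    def test_matches_bfs_oracles_on_unweighted_graphs(self):
        for seed in range(3):
            g = nx.gnp_random_graph(16, 0.25, seed=seed)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
            tab = centralities(g).set_index("gene")
            bc = oracle.betweenness(g)
            for u in g:
                assert tab.loc[u, "closeness"] == pytest.approx(oracle.closeness(g, u))
                assert tab.loc[u, "betweenness"] == pytest.approx(bc[u], abs=1e-9)

    def test_transform_changes_weighted_paths(self):
        # reciprocal prefers heavy edges as short hops; raw does the opposite
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("b", "c", weight=0.9)
        g.add_edge("a", "c", weight=0.2)
        rec = centralities(g, "reciprocal").set_index("gene")
        raw = centralities(g, "raw").set_index("gene")
        assert rec.loc["b", "betweenness"] > 0.0  # detour via b is shorter
        assert raw.loc["b", "betweenness"] == pytest.approx(0.0)

    def test_modular_graph_clusters_more_than_degree_null(self):
        # planted cliques vs expected-degree graphs of the same sequence
        from tecnet import build_network, expected_degree_graph
        from tecnet.simulate import simulate_covariation_pair

        blocks = [list(range(i, i + 6)) for i in range(0, 30, 6)]
        cov, _ = simulate_covariation_pair(40, blocks, [], [], 0.9, seed=21)
        g = build_network(cov, 0.75)
        obs = clustering_coefficients(g)["clustering"].mean()
        ds = [d for _, d in g.degree()]
        null_means = [
            clustering_coefficients(expected_degree_graph(ds, seed=s))[
                "clustering"
            ].mean()
            for s in range(10)
        ]
        assert obs > np.mean(null_means)
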