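import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tecnet import (
    build_network,
    centrality_imbalance,
    connectivity_shift,
    cv_by_abundance,
    edge_retention_check,
    neighborhood_jaccard,
    select_connectivity_extremes,
    simulate_covariation_pair,
)
from tecnet.matrices import CovariationMatrix

from conftest import random_weighted_graph
import _oracles as oracle


class TestNeighborhoodJaccard:
    def test_identical_graphs_score_one(self, small_weighted_graph):
        rep = neighborhood_jaccard(small_weighted_graph, small_weighted_graph)
        assert (rep["jaccard"] == 1.0).all()

    def test_partial_overlap_hand_computed(self):
        ga = nx.Graph([("u", "a"), ("u", "b"), ("u", "c"), ("a", "b")])
        gb = nx.Graph([("u", "b"), ("u", "c"), ("u", "d"), ("b", "c")])
        rep = neighborhood_jaccard(ga, gb).set_index("gene")
        assert rep.loc["u", "jaccard"] == pytest.approx(0.5)  # {b,c} / {a,b,c,d}

    def test_matches_set_oracle_on_synthetic_pair(self):
        ca, cb = simulate_covariation_pair(
            40, [[0, 1, 2, 3]], [[4, 5, 6]], [[7, 8, 9]], 0.9, seed=30
        )
        ga, gb = build_network(ca, 0.75), build_network(cb, 0.75)
        shared = set(ga) & set(gb)
        if shared:
            rep = neighborhood_jaccard(ga, gb).set_index("gene")
            for u in shared:
                assert rep.loc[u, "jaccard"] == pytest.approx(oracle.jaccard(ga, gb, u))

    def test_symmetric_in_arguments(self):
        ga = random_weighted_graph(15, 0.3, 31)
        gb = random_weighted_graph(15, 0.3, 32)
        ja = neighborhood_jaccard(ga, gb).set_index("gene")["jaccard"]
        jb = neighborhood_jaccard(gb, ga).set_index("gene")["jaccard"]
        assert (ja == jb.reindex(ja.index)).all()

    def test_jaccard_one_iff_identical_neighbor_sets(self):
        ga = random_weighted_graph(12, 0.4, 33)
        gb = random_weighted_graph(12, 0.4, 34)
        rep = neighborhood_jaccard(ga, gb)
        for _, row in rep.iterrows():
            same = set(ga.neighbors(row["gene"])) == set(gb.neighbors(row["gene"]))
            assert (row["jaccard"] == 1.0) == same

    def test_no_overlap_rejected(self):
        ga, gb = nx.Graph([("a", "b")]), nx.Graph([("c", "d")])
        with pytest.raises(ValueError):
            neighborhood_jaccard(ga, gb)


class TestCentralityImbalance:
    def test_identical_graphs_zero_difference(self, small_weighted_graph):
        tab = centrality_imbalance(small_weighted_graph, small_weighted_graph)
        assert np.allclose(tab["difference"], 0.0)

    def test_strength_difference_recomputed_per_gene(self):
        ga = nx.Graph()
        ga.add_edge("x", "a", weight=0.95)
        ga.add_edge("x", "b", weight=0.85)
        ga.add_edge("a", "b", weight=0.8)
        gb = nx.Graph()
        gb.add_edge("x", "a", weight=0.76)
        gb.add_edge("a", "b", weight=0.9)
        tab = centrality_imbalance(ga, gb, "strength").set_index("gene")
        assert tab.loc["x", "difference"] == pytest.approx((0.95 + 0.85) - 0.76)

    def test_ranked_by_absolute_difference(self):
        ga = random_weighted_graph(15, 0.3, 35)
        gb = random_weighted_graph(15, 0.3, 36)
        tab = centrality_imbalance(ga, gb, "closeness")
        diffs = tab["difference"].abs().to_numpy()
        assert (np.diff(diffs) <= 1e-12).all()

    def test_unknown_measure_rejected(self, small_weighted_graph):
        with pytest.raises(ValueError):
            centrality_imbalance(small_weighted_graph, small_weighted_graph, "pagerank")


class TestEdgeRetention:
    def _cov(self, scores, genes):
        return CovariationMatrix(genes, scores)

    def test_identical_weights_all_fractions_zero(self):
        ga = nx.Graph()
        ga.add_edge("g0", "g1", weight=0.8)
        ga.add_edge("g0", "g2", weight=0.9)
        s = np.eye(3)
        s[0, 1] = s[1, 0] = 0.8
        s[0, 2] = s[2, 0] = 0.9
        fr = edge_retention_check(ga, self._cov(s, ["g0", "g1", "g2"]), "g0", [0.1])
        assert fr == {0.1: 0.0}

    def test_constant_gap(self):
        ga = nx.Graph()
        for v in ("g1", "g2", "g3"):
            ga.add_edge("g0", v, weight=0.8)
        s = np.eye(4)
        for i in (1, 2, 3):
            s[0, i] = s[i, 0] = 0.55
        fr = edge_retention_check(
            ga, self._cov(s, ["g0", "g1", "g2", "g3"]), "g0", [0.1, 0.3]
        )
        assert fr == {0.1: 1.0, 0.3: 0.0}

    def test_missing_gene_rejected(self):
        ga = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            edge_retention_check(ga, self._cov(np.eye(2), ["a", "b"]), "zz", [0.1])


class TestConnectivityShift:
    def test_absent_gene_reports_zero_with_flag(self):
        ga = nx.Graph([("a", "b")])
        gb = nx.star_graph(5)
        gb = nx.relabel_nodes(gb, {0: "x", 1: "a", 2: "b", 3: "c", 4: "d", 5: "e"})
        tab = connectivity_shift(ga, gb, ["x", "a"]).set_index("gene")
        assert tab.loc["x", "degree_A"] == 0 and not tab.loc["x", "present_A"]
        assert tab.loc["x", "degree_B"] == 5

    def test_identical_graphs_equal_pairs(self, small_weighted_graph):
        tab = connectivity_shift(
            small_weighted_graph, small_weighted_graph, list(small_weighted_graph)
        )
        assert (tab["degree_A"] == tab["degree_B"]).all()

    def test_block_specific_to_b_shifts_positively(self):
        block = [0, 1, 2, 3, 4]
        ca, cb = simulate_covariation_pair(30, [], [], [block], 0.9, seed=37)
        ga, gb = build_network(ca, 0.75), build_network(cb, 0.75)
        names = [f"G{i:04d}" for i in block]
        tab = connectivity_shift(ga, gb, names)
        assert (tab["degree_B"] == len(block) - 1).all()
        assert (tab["degree_A"] == 0).all()


class TestSelectConnectivityExtremes:
    def _setup(self):
        ca, _ = simulate_covariation_pair(
            30, [[0, 1, 2, 3, 4, 5]], [], [], 0.9, seed=38
        )
        g = build_network(ca, 0.75)
        return g, ca

    def test_deterministic_for_fixed_seed(self):
        g, cov = self._setup()
        a = select_connectivity_extremes(g, cov, 3, 5, seed=1)
        b = select_connectivity_extremes(g, cov, 3, 5, seed=1)
        assert a == b

    def test_isolated_sample_disjoint_from_graph(self):
        g, cov = self._setup()
        top, iso = select_connectivity_extremes(g, cov, 3, 5, seed=2)
        assert not (set(iso) & set(g.nodes()))
        assert set(top) <= set(g.nodes())

    def test_tie_handling_matches_stable_sort_oracle(self):
        g, cov = self._setup()
        top, _ = select_connectivity_extremes(g, cov, 6, 1, seed=3)
        deg = dict(g.degree())
        stren = dict(g.degree(weight="weight"))
        expect = sorted(g.nodes(), key=lambda u: (-deg[u], -stren[u], str(u)))[:6]
        assert top == [str(u) for u in expect]

    def test_insufficient_isolated_rejected(self):
        g, cov = self._setup()
        with pytest.raises(ValueError):
            select_connectivity_extremes(g, cov, 3, 1000, seed=0)


class TestCVByAbundance:
    def _table(self):
        rng = np.random.default_rng(40)
        genes = [f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)]
        base = rng.uniform(10, 1000, size=60)
        tissues = {}
        profile = rng.uniform(0.5, 1.5, size=8)
        for t in range(8):
            noise = rng.normal(1.0, 0.05, size=60)
            tissues[f"T{t}"] = base * profile[t] * noise
        return pd.DataFrame(tissues, index=genes)

    def test_constant_profile_has_zero_cv(self):
        df = pd.DataFrame({"T1": [5.0, 2.0], "T2": [5.0, 3.0], "T3": [5.0, 4.0]},
                          index=["flat", "vary"])
        prof = cv_by_abundance(df, ["flat"], ["vary"], n_bins=1)
        per = prof.per_gene.set_index("gene")
        assert per.loc["flat", "cv"] == 0.0

    def test_two_point_cv_hand_computed(self):
        df = pd.DataFrame({"T1": [1.0], "T2": [3.0]}, index=["g"])
        prof = cv_by_abundance(df, ["g"], ["g"], n_bins=1)
        assert prof.per_gene["cv"].iloc[0] == pytest.approx(np.sqrt(2) / 2)

    def test_inflated_noise_recovers_cv_ratio(self):
        # group B = same means, deviations scaled 1.5x => CV ratio exactly 1.5
        df = self._table()
        a_genes = [f"a{i}" for i in range(30)]
        b = df.loc[a_genes].to_numpy()
        mean = b.mean(axis=1, keepdims=True)
        inflated = mean + 1.5 * (b - mean)
        df.loc[[f"b{i}" for i in range(30)]] = inflated
        prof = cv_by_abundance(df, a_genes, [f"b{i}" for i in range(30)], n_bins=5)
        # binning by rank may split an (A, B) twin across a bin boundary,
        # so the recovered ratio is near-exact rather than exact
        assert prof.mean_ratio == pytest.approx(1.5, rel=0.1)

    def test_too_few_tissues_rejected(self):
        df = pd.DataFrame({"T1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            cv_by_abundance(df, ["a"], ["b"], n_bins=1)
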