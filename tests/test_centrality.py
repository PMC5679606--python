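import networkx as nx
import numpy as np
import pytest

from diffslc.centrality import (
    betweenness_centrality,
    biased_degree_centrality,
    closeness_centrality,
    compute_centrality,
    degree_centrality,
    diffslc,
    eigenvector_centrality,
    subgraph_centrality,
)
from diffslc.network import EdgeWeights, all_edge_weights, edge_key
from conftest import random_graph, uniform_weights
from oracles import (
    betweenness_bruteforce,
    expm_diag_taylor,
    harmonic_closeness_bruteforce,
)


class TestDegree:
    def test_isolated_node_scores_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("P20")  # a protein with no interaction partner
        assert degree_centrality(g)["P20"] == 0.0

    def test_complete_graph(self):
        g = nx.complete_graph(6)
        assert all(s == 5.0 for s in degree_centrality(g).scores.values())

    def test_star(self, star4):
        scores = degree_centrality(star4)
        assert scores["n0"] == 4.0
        assert all(scores[f"n{i}"] == 1.0 for i in range(1, 5))


class TestCloseness:
    def test_path3_harmonic_values(self, path3):
        scores = closeness_centrality(path3)
        assert scores["b"] == pytest.approx(2.0)
        assert scores["a"] == pytest.approx(1.5)

    def test_isolated_node_is_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("solo")
        assert closeness_centrality(g)["solo"] == 0.0

    def test_matches_bfs_oracle_on_disconnected_graph(self):
        rng = np.random.default_rng(31)
        g = nx.fast_gnp_random_graph(40, 0.05, seed=2)
        scores = closeness_centrality(g)
        for node, expected in harmonic_closeness_bruteforce(g).items():
            assert scores[node] == pytest.approx(expected, abs=1e-12)

    def test_classic_mode_is_inverse_farness(self, path3):
        scores = closeness_centrality(path3, mode="classic")
        assert scores["b"] == pytest.approx(1.0 / 2.0)
        assert scores["a"] == pytest.approx(1.0 / 3.0)


class TestBetweenness:
    def test_tree_leaves_are_zero(self):
        tree = nx.random_labeled_tree(10, seed=4)
        scores = betweenness_centrality(tree)
        for leaf in (n for n in tree.nodes() if tree.degree(n) == 1):
            assert scores[leaf] == 0.0

    def test_star_center_counts_all_pairs(self, star4):
        assert betweenness_centrality(star4)["n0"] == pytest.approx(6.0)  # C(4,2)

    def test_path3_center(self, path3):
        assert betweenness_centrality(path3)["b"] == pytest.approx(1.0)

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(5):
            g = random_graph(rng, n_max=25, p=0.2)
            scores = betweenness_centrality(g)
            for node, expected in betweenness_bruteforce(g).items():
                assert scores[node] == pytest.approx(expected, abs=1e-9)


class TestEigenvector:
    def test_complete_graph_all_ones(self):
        g = nx.complete_graph(5)
        assert all(s == pytest.approx(1.0) for s in eigenvector_centrality(g).scores.values())

    def test_path3_known_ratio(self, path3):
        scores = eigenvector_centrality(path3)
        assert scores["b"] == pytest.approx(1.0)
        assert scores["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-10)

    def test_star_leaf_to_center_ratio(self, star4):
        scores = eigenvector_centrality(star4)  # lambda = 2 for a 4-leaf star
        assert scores["n1"] == pytest.approx(0.5, abs=1e-10)

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(41)
        g = random_graph(rng, n_max=40, p=0.2)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        nodes = sorted(g.nodes())
        adj = nx.to_numpy_array(g, nodelist=nodes)
        eigvals, eigvecs = np.linalg.eigh(adj)
        principal = np.abs(eigvecs[:, -1])
        principal /= principal.max()
        scores = eigenvector_centrality(g)
        for i, node in enumerate(nodes):
            assert scores[node] == pytest.approx(principal[i], abs=1e-8)

    def test_eigen_residual_small(self):
        rng = np.random.default_rng(43)
        g = random_graph(rng, n_max=50, p=0.15)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        nodes = sorted(g.nodes())
        adj = nx.to_numpy_array(g, nodelist=nodes)
        x = np.array([eigenvector_centrality(g)[n] for n in nodes])
        x /= np.linalg.norm(x)
        lam = x @ adj @ x
        assert np.linalg.norm(adj @ x - lam * x) <= 1e-10

    def test_bipartite_component_converges(self):
        g = nx.complete_bipartite_graph(3, 4)
        scores = eigenvector_centrality(g)
        assert max(scores.scores.values()) == pytest.approx(1.0)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(nx.Graph())

    def test_weighted_adjacency_mode(self, path3):
        weights = {("a", "b"): 2.0, ("b", "c"): 1.0}
        scores = eigenvector_centrality(path3, weights=weights)
        # principal eigenvector of [[0,2,0],[2,0,1],[0,1,0]]
        adj = np.array([[0, 2, 0], [2, 0, 1], [0, 1, 0.0]])
        vec = np.abs(np.linalg.eigh(adj)[1][:, -1])
        vec /= vec.max()
        for node, expected in zip(["a", "b", "c"], vec):
            assert scores[node] == pytest.approx(expected, abs=1e-10)


class TestSubgraph:
    def test_isolated_node_is_one(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("solo")
        assert subgraph_centrality(g)["solo"] == pytest.approx(1.0)

    def test_single_edge_is_cosh_one(self):
        g = nx.Graph()
        g.add_edge("u", "v")
        scores = subgraph_centrality(g)
        assert scores["u"] == pytest.approx(np.cosh(1.0), abs=1e-12)

    def test_triangle_closed_form(self, triangle):
        expected = np.exp(2) / 3 + 2 * np.exp(-1) / 3
        assert subgraph_centrality(triangle)["a"] == pytest.approx(expected, abs=1e-12)

    def test_matches_taylor_series_of_matrix_exponential(self):
        rng = np.random.default_rng(47)
        g = random_graph(rng, n_max=50, p=0.15)
        nodes = sorted(g.nodes())
        diag = expm_diag_taylor(nx.to_numpy_array(g, nodelist=nodes))
        scores = subgraph_centrality(g)
        for i, node in enumerate(nodes):
            assert scores[node] == pytest.approx(diag[i], abs=1e-8)

    def test_size_guard(self):
        g = nx.path_graph(10)
        with pytest.raises(ValueError, match="guard"):
            subgraph_centrality(g, dense_limit=5)


class TestBiasedDegree:
    @staticmethod
    def _two_edge_graph():
        g = nx.Graph()
        g.add_edges_from([("u", "a"), ("u", "b")])
        w = EdgeWeights(
            ecc={("a", "u"): 2.0, ("b", "u"): 0.0},
            coexpr={("a", "u"): 0.5, ("b", "u"): 1.0},
        )
        return g, w

    def test_hand_computed_mix(self):
        g, w = self._two_edge_graph()
        assert biased_degree_centrality(g, w, beta=0.8)["u"] == pytest.approx(1.6)

    def test_beta_zero_is_ecc_sum(self):
        g, w = self._two_edge_graph()
        scores = biased_degree_centrality(g, w, beta=0.0)
        assert scores["u"] == pytest.approx(2.0)

    def test_beta_one_is_coexpression_sum(self):
        g, w = self._two_edge_graph()
        scores = biased_degree_centrality(g, w, beta=1.0)
        assert scores["u"] == pytest.approx(1.5)

    def test_beta_out_of_range_rejected(self):
        g, w = self._two_edge_graph()
        with pytest.raises(ValueError):
            biased_degree_centrality(g, w, beta=1.2)

    def test_constant_weights_make_bdc_proportional_to_degree(self):
        rng = np.random.default_rng(53)
        g = random_graph(rng, n_max=40)
        w = uniform_weights(g, coexpr=0.0, ecc=0.7)
        scores = biased_degree_centrality(g, w, beta=0.3)
        for n in g.nodes():
            assert scores[n] == pytest.approx(0.7 * 0.7 * g.degree(n), abs=1e-12)


class TestDiffSLC:
    @staticmethod
    def _weighted(net):
        rng = np.random.default_rng(59)
        coexpr = {edge_key(u, v): float(rng.uniform(0, 1)) for u, v in net.edges()}
        return all_edge_weights(net, coexpr)

    def test_omega_one_reduces_to_eigenvector(self):
        rng = np.random.default_rng(61)
        g = random_graph(rng, n_max=30)
        w = self._weighted(g)
        scores = diffslc(g, w, omega=1.0)
        ec = eigenvector_centrality(g)
        for n in g.nodes():
            assert scores[n] == pytest.approx(ec[n], abs=1e-12)

    def test_omega_zero_reduces_to_bdc(self):
        rng = np.random.default_rng(67)
        g = random_graph(rng, n_max=30)
        w = self._weighted(g)
        scores = diffslc(g, w, beta=0.4, omega=0.0)
        bdc = biased_degree_centrality(g, w, beta=0.4)
        for n in g.nodes():
            assert scores[n] == pytest.approx(bdc[n], abs=1e-12)

    def test_hand_computed_combination(self):
        g = nx.Graph()
        g.add_edge("u", "v")
        w = EdgeWeights(ecc={("u", "v"): 0.0}, coexpr={("u", "v"): 0.0})
        ec = eigenvector_centrality(g)
        from diffslc.centrality import CentralityScores
        ec_fixed = CentralityScores("ec", {"u": 0.5, "v": 1.0})
        bdc_fixed = CentralityScores("bdc", {"u": 1.6, "v": 0.2}, {"beta": 0.8})
        scores = diffslc(g, w, beta=0.8, omega=0.1,
                         ec_scores=ec_fixed, bdc_scores=bdc_fixed)
        assert scores["u"] == pytest.approx(0.1 * 0.5 + 0.9 * 1.6)

    def test_affine_in_omega_per_node(self):
        rng = np.random.default_rng(71)
        g = random_graph(rng, n_max=30)
        w = self._weighted(g)
        low = diffslc(g, w, omega=0.0)
        high = diffslc(g, w, omega=1.0)
        mid = diffslc(g, w, omega=0.5)
        for n in g.nodes():
            assert mid[n] == pytest.approx((low[n] + high[n]) / 2, abs=1e-12)

    def test_minmax_normalization_bounds_scores(self):
        rng = np.random.default_rng(73)
        g = random_graph(rng, n_max=30)
        w = self._weighted(g)
        scores = diffslc(g, w, normalization="minmax")
        values = list(scores.scores.values())
        assert min(values) >= 0.0 and max(values) <= 1.0

    def test_params_recorded(self):
        g = nx.complete_graph(4)
        w = uniform_weights(g)
        scores = diffslc(g, w, beta=0.8, omega=0.1)
        assert scores.params["beta"] == 0.8 and scores.params["omega"] == 0.1


def test_all_centralities_invariant_under_relabeling():
    rng = np.random.default_rng(79)
    g = random_graph(rng, n_max=25, p=0.25)
    mapping = {n: f"Q{n:03d}" for n in rng.permutation(list(g.nodes()))}
    h = nx.relabel_nodes(g, mapping)
    for method in ("dc", "cc", "bc", "ec", "sc"):
        original = compute_centrality(method, g)
        relabeled = compute_centrality(method, h)
        for n in g.nodes():
            assert relabeled[mapping[n]] == pytest.approx(original[n], abs=1e-8)


def test_dispatcher_rejects_unknown_method():
    with pytest.raises(ValueError, match="unknown centrality"):
        compute_centrality("pagerank", nx.complete_graph(3))
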