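"""Edge filtering, CPL, ND and eigenvector centrality."""

import numpy as np
import pytest

from conftest import random_distance
from oracles import floyd_warshall
from phnet.connectivity import DistanceMatrix
from phnet.graph_metrics import (
    WeightedGraph,
    characteristic_path_length,
    eigenvector_centrality,
    filter_edges,
    network_diameter,
)


def graph_of(n, edges):
    return WeightedGraph([f"r{i}" for i in range(n)], edges, {"rule": "manual"})


class TestFilterEdges:
    def test_threshold_one_gives_complete_graph(self, four_node_dist):
        g = filter_edges(four_node_dist, threshold=1.0)
        assert len(g.edges) == 6

    def test_threshold_below_minimum_gives_empty_graph(self, four_node_dist):
        g = filter_edges(four_node_dist, threshold=0.05)
        assert g.edges == []

    def test_worked_example_at_half(self, four_node_dist):
        g = filter_edges(four_node_dist, threshold=0.5)
        kept = {(i, j): w for i, j, w in g.edges}
        assert kept == {(0, 1): 0.1, (1, 2): 0.3, (0, 2): 0.4, (2, 3): 0.5}
        assert g.retain_rule == {"rule": "threshold", "threshold": 0.5}

    def test_density_rule_keeps_strongest_fraction(self, four_node_dist):
        g = filter_edges(four_node_dist, rule="density", density=0.5)
        assert sorted(w for _, _, w in g.edges) == [0.1, 0.3, 0.4]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_out_of_range_refused(self, four_node_dist, bad):
        with pytest.raises(ValueError):
            filter_edges(four_node_dist, threshold=bad)


class TestPathMetrics:
    def test_worked_example_cpl_and_nd(self, four_node_dist):
        g = filter_edges(four_node_dist, threshold=1.0)
        # shortest paths: AB .1, AC .4, AD .9, BC .3, BD .8, CD .5
        cpl = characteristic_path_length(g)
        assert cpl.value == pytest.approx(0.5, abs=1e-12)
        assert cpl.n_disconnected_pairs == 0
        nd = network_diameter(g)
        assert nd.value == pytest.approx(0.9, abs=1e-12)

    def test_two_nodes_single_edge(self):
        g = graph_of(2, [(0, 1, 0.7)])
        assert characteristic_path_length(g).value == pytest.approx(0.7)
        assert network_diameter(g).value == pytest.approx(0.7)

    def test_path_graph_closed_form(self):
        g = graph_of(3, [(0, 1, 1.0), (1, 2, 1.0)])
        assert characteristic_path_length(g).value == pytest.approx((1 + 1 + 2) / 3)

    def test_star_graph_diameter(self):
        g = graph_of(5, [(0, k, 1.0) for k in range(1, 5)])
        assert network_diameter(g).value == pytest.approx(2.0)

    def test_disconnected_pairs_excluded_and_counted(self):
        g = graph_of(4, [(0, 1, 0.2), (2, 3, 0.4)])
        cpl = characteristic_path_length(g)
        assert cpl.value == pytest.approx(0.3)
        assert cpl.n_disconnected_pairs == 4

    def test_no_connected_pair_is_undefined_not_zero(self):
        g = graph_of(3, [])
        cpl = characteristic_path_length(g)
        assert cpl.value is None
        assert cpl.n_disconnected_pairs == 3

    def test_cpl_never_exceeds_nd(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = random_distance(rng, int(rng.integers(4, 10)))
            g = filter_edges(d, threshold=float(rng.uniform(0.3, 1.0)))
            if not g.edges:
                continue
            cpl, nd = characteristic_path_length(g), network_diameter(g)
            assert cpl.value <= nd.value + 1e-12

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            d = random_distance(rng, n)
            g = filter_edges(d, threshold=float(rng.uniform(0.4, 1.0)))
            sp = floyd_warshall(g.length_matrix())
            iu = np.triu_indices(n, 1)
            vals = sp[iu]
            finite = np.isfinite(vals)
            cpl, nd = characteristic_path_length(g), network_diameter(g)
            if not finite.any():
                assert cpl.value is None
                continue
            assert cpl.value == pytest.approx(vals[finite].mean(), abs=1e-12)
            assert nd.value == pytest.approx(vals[finite].max(), abs=1e-12)
            assert cpl.n_disconnected_pairs == int((~finite).sum())

    def test_removing_edges_never_decreases_cpl(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            d = random_distance(rng, 8)
            loose = characteristic_path_length(filter_edges(d, threshold=1.0))
            tight_g = filter_edges(d, threshold=0.6)
            if not tight_g.edges:
                continue
            tight = characteristic_path_length(tight_g)
            if tight.value is not None and tight.n_disconnected_pairs == 0:
                assert tight.value >= loose.value - 1e-12


class TestEigenvectorCentrality:
    def test_complete_equal_weights_all_scores_one(self):
        g = graph_of(4, [(i, j, 0.5) for i in range(4) for j in range(i + 1, 4)])
        scores = eigenvector_centrality(g)
        assert all(s == pytest.approx(1.0, abs=1e-9) for s in scores.values())

    def test_star_hub_dominates(self):
        g = graph_of(5, [(0, k, 0.5) for k in range(1, 5)])
        scores = eigenvector_centrality(g)
        assert scores["r0"] == pytest.approx(1.0)
        assert all(scores[f"r{k}"] < 1.0 for k in range(1, 5))

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            d = random_distance(rng, 6, max_d=0.9)
            g = filter_edges(d, threshold=1.0)
            scores = np.array(list(eigenvector_centrality(g).values()))
            adj = np.where(g.length_matrix() > 0, 1.0 - g.length_matrix(), 0.0)
            eigval, eigvec = np.linalg.eigh(adj)
            perron = np.abs(eigvec[:, -1])
            np.testing.assert_allclose(scores, perron / perron.max(), atol=1e-8)

    def test_eigen_equation_residual(self):
        rng = np.random.default_rng(19)
        d = random_distance(rng, 8, max_d=0.9)
        g = filter_edges(d, threshold=1.0)
        v = np.array(list(eigenvector_centrality(g).values()))
        v = v / np.linalg.norm(v)
        adj = np.where(g.length_matrix() > 0, 1.0 - g.length_matrix(), 0.0)
        mu = v @ adj @ v
        assert np.linalg.norm(adj @ v - mu * v) <= 1e-8

    def test_disconnected_graph_warns_and_uses_largest_component(self):
        g = graph_of(5, [(0, 1, 0.2), (1, 2, 0.3), (3, 4, 0.4)])
        with pytest.warns(UserWarning, match="largest"):
            scores = eigenvector_centrality(g)
        assert scores["r3"] == 0.0 and scores["r4"] == 0.0
        assert max(scores.values()) == pytest.approx(1.0)

    def test_empty_graph_refused(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(graph_of(3, []))
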