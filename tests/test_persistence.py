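"""Zero-dimensional persistence: MST, Betti-0, barcode, SLD, SIP AUC."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform

from conftest import random_distance
from oracles import component_count_at, minimax_path_exhaustive, mst_total_exhaustive
from phnet.connectivity import DistanceMatrix
from phnet.persistence import (
    analyze_distance,
    barcode,
    betti0_curve,
    compute_mst,
    single_linkage,
    sip_auc,
    snapshot_graph,
    to_newick,
)


def dist_of(d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(d=d, roi_names=[f"r{i}" for i in range(d.shape[0])])


class TestWorkedFourNodeExample:
    """The hand-checked 4-ROI fixture: every facet has a known exact value."""

    def test_mst_weights_and_total(self, four_node_dist):
        mst = compute_mst(four_node_dist)
        assert sorted(w for _, _, w in mst) == [0.1, 0.3, 0.5]
        assert sum(w for _, _, w in mst) == pytest.approx(0.9, abs=1e-15)
        assert sum(w for _, _, w in mst) == pytest.approx(
            mst_total_exhaustive(four_node_dist.d), abs=1e-15
        )

    def test_betti0_sequence(self, four_node_dist):
        curve = betti0_curve(four_node_dist)
        np.testing.assert_allclose(curve.breakpoints, [0.1, 0.3, 0.5])
        np.testing.assert_array_equal(curve.counts, [4, 3, 2, 1])
        # right-continuity at a breakpoint: edge present iff d <= lambda
        assert curve(0.05) == 4 and curve(0.1) == 3 and curve(0.3) == 2
        assert curve(0.5) == 1 and curve(1.0) == 1

    def test_barcode_deaths(self, four_node_dist):
        bc = barcode(four_node_dist)
        assert len(bc.bars) == 4
        assert all(b == 0.0 for b, _ in bc.bars)
        assert bc.finite_deaths == [0.1, 0.3, 0.5]
        assert max(d for _, d in bc.bars) == 1.0

    def test_single_linkage_ultrametric(self, four_node_dist):
        sld = single_linkage(four_node_dist).sld
        A, B, C, D = range(4)
        assert sld[A, B] == 0.1
        assert sld[A, C] == sld[B, C] == 0.3
        assert sld[A, D] == sld[B, D] == sld[C, D] == 0.5

    def test_sip_auc_hand_integration(self, four_node_dist):
        # 4*0.1 + 3*0.2 + 2*0.2 + 1*0.5 = 1.9 = 1 + MST total
        auc = sip_auc(betti0_curve(four_node_dist))
        assert auc == pytest.approx(1.9, abs=1e-12)

    def test_snapshots(self, four_node_dist):
        empty = snapshot_graph(four_node_dist, 0.0)
        assert empty.edges == [] and empty.n_components == 4
        full = snapshot_graph(four_node_dist, 1.0)
        assert len(full.edges) == 6 and full.n_components == 1
        snap = snapshot_graph(four_node_dist, 0.25)
        assert [(i, j) for i, j, _ in snap.edges] == [(0, 1)]
        labels = snap.component_labels
        assert labels[0] == labels[1] and len(set(labels)) == 3


class TestDegenerateAndTiedInputs:
    def test_two_rois(self):
        d = dist_of([[0, 0.3], [0.3, 0]])
        assert compute_mst(d) == [(0, 1, 0.3)]
        bc = barcode(d)
        assert sorted(bc.bars) == [(0.0, 0.3), (0.0, 1.0)]
        assert sip_auc(betti0_curve(d)) == pytest.approx(1.3)

    @pytest.mark.parametrize("n,w", [(3, 0.2), (6, 0.45)])
    def test_all_equal_distances(self, n, w):
        d = dist_of(np.full((n, n), w) - w * np.eye(n))
        mst = compute_mst(d)
        assert sum(x for _, _, x in mst) == pytest.approx((n - 1) * w, abs=1e-12)
        curve = betti0_curve(d)
        np.testing.assert_array_equal(curve.counts, [n, 1])  # all merge at once
        assert barcode(d).finite_deaths == [w] * (n - 1)

    def test_all_zero_distances_single_component_everywhere(self):
        d = dist_of(np.zeros((4, 4)))
        curve = betti0_curve(d)
        assert curve(0.0) == 1
        assert sip_auc(curve) == pytest.approx(1.0)

    def test_identity_correlation_distance_stays_disconnected(self):
        n = 5
        d = dist_of(np.ones((n, n)) - np.eye(n))
        curve = betti0_curve(d)
        assert curve(0.99) == n and curve(1.0) == 1
        assert sip_auc(curve) == pytest.approx(n)  # the ceiling case

    def test_single_roi_refused(self):
        d = DistanceMatrix(np.zeros((1, 1)), ["only"])
        with pytest.raises(ValueError):
            compute_mst(d)
        with pytest.raises(ValueError):
            single_linkage(d)

    def test_lambda_outside_range_refused(self, four_node_dist):
        with pytest.raises(ValueError):
            snapshot_graph(four_node_dist, 1.2)
        with pytest.raises(ValueError):
            snapshot_graph(four_node_dist, -0.1)


class TestAgainstIndependentImplementations:
    """Cross-checks against scipy and the brute-force oracles."""

    @pytest.mark.parametrize("seed", range(5))
    def test_mst_total_matches_scipy_csgraph(self, seed):
        rng = np.random.default_rng(seed)
        d = random_distance(rng, 10)
        mine = sum(w for _, _, w in compute_mst(d))
        ref = minimum_spanning_tree(d.d).sum()
        assert mine == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_mst_total_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = random_distance(rng, 6)
        mine = sum(w for _, _, w in compute_mst(d))
        assert mine == pytest.approx(mst_total_exhaustive(d.d), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_match_scipy_single_linkage(self, seed):
        rng = np.random.default_rng(200 + seed)
        d = random_distance(rng, 9)
        heights = sorted(w for w, _, _ in single_linkage(d).merge_tree)
        ref = sorted(linkage(squareform(d.d), method="single")[:, 2])
        np.testing.assert_allclose(heights, ref, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_sld_matches_exhaustive_minimax_paths(self, seed):
        rng = np.random.default_rng(300 + seed)
        d = random_distance(rng, 6)
        sld = single_linkage(d).sld
        for a in range(6):
            for b in range(a + 1, 6):
                assert sld[a, b] == pytest.approx(
                    minimax_path_exhaustive(d.d, a, b), abs=1e-12
                )

    def test_betti_curve_matches_union_find(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            d = random_distance(rng, int(rng.integers(4, 12)))
            curve = betti0_curve(d)
            for lam in rng.uniform(0, 1, size=3):
                assert curve(float(lam)) == component_count_at(d.d, float(lam))


class TestStructuralInvariants:
    def test_sld_is_ultrametric_and_below_input(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            d = random_distance(rng, 8)
            sld = single_linkage(d).sld
            assert np.all(sld <= d.d + 1e-12)
            n = 8
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert sld[i, k] <= max(sld[i, j], sld[j, k]) + 1e-12

    def test_ultrametric_input_is_fixed_point(self, four_node_dist):
        sld1 = single_linkage(four_node_dist).sld
        d2 = DistanceMatrix(sld1, four_node_dist.roi_names)
        np.testing.assert_allclose(single_linkage(d2).sld, sld1, atol=1e-15)

    def test_max_sld_equals_largest_mst_weight(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            d = random_distance(rng, 7)
            sld = single_linkage(d).sld
            top = max(w for _, _, w in compute_mst(d))
            assert sld.max() == pytest.approx(top, abs=1e-15)

    def test_decreasing_an_edge_never_increases_sip_auc(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            d = random_distance(rng, 7)
            before = sip_auc(betti0_curve(d))
            m = d.d.copy()
            i, j = rng.integers(0, 7, size=2)
            while i == j:
                j = rng.integers(0, 7)
            m[i, j] = m[j, i] = m[i, j] * rng.uniform(0, 1)
            after = sip_auc(betti0_curve(DistanceMatrix(m, d.roi_names)))
            assert after <= before + 1e-12

    @pytest.mark.parametrize("c", [0.2, 0.5, 1.0])
    def test_scale_equivariance_of_mst_total(self, c):
        rng = np.random.default_rng(51)
        d = random_distance(rng, 9)
        base = sum(w for _, _, w in compute_mst(d))
        scaled = DistanceMatrix(c * d.d, d.roi_names)
        total = sum(w for _, _, w in compute_mst(scaled))
        assert total == pytest.approx(c * base, abs=1e-12)
        assert sip_auc(betti0_curve(scaled)) - 1 == pytest.approx(c * base, abs=1e-9)


class TestNewickExport:
    def test_dendropy_parses_and_leaf_depths_are_merge_heights(self, four_node_dist):
        import dendropy

        tree = dendropy.Tree.get(
            data=to_newick(single_linkage(four_node_dist)), schema="newick"
        )
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == {"A", "B", "C", "D"}
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        sld = single_linkage(four_node_dist).sld
        names = four_node_dist.roi_names
        for i in range(4):
            for j in range(i + 1, 4):
                # ultrametric tree: leaf-to-leaf path length = 2 * merge height
                got = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
                assert got == pytest.approx(2 * sld[i, j], abs=1e-9)


def test_analyze_distance_bundles_consistent_facets(four_node_dist):
    res = analyze_distance(four_node_dist)
    assert res.sip_auc == pytest.approx(1.0 + res.mst_total, abs=1e-12)
    assert sorted(res.barcode.finite_deaths) == sorted(w for _, _, w in res.mst_edges)
    merge_heights = sorted(w for w, _, _ in res.single_linkage.merge_tree)
    assert merge_heights == sorted(w for _, _, w in res.mst_edges)
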