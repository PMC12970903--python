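"""Binarization, topology metrics, small-worldness, grid validation, AUC."""

import networkx as nx
import numpy as np
import pytest

from scnkit import (SparsityGrid, auc, binarize, characteristic_path_length,
                    clustering_coefficient, degree_and_betweenness,
                    global_efficiency, local_efficiency, metric_curves,
                    shortest_path_lengths, small_world_index,
                    validate_sparsity_grid)
from scnkit.graph_metrics import edge_ranking, n_edges_at

from .conftest import random_graph
from .oracles import (brute_betweenness, brute_clustering,
                      brute_global_efficiency, brute_local_efficiency,
                      brute_path_length, floyd_warshall, trapezoid_sum)


def adjacency(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


TRIANGLE = adjacency(3, [(0, 1), (1, 2), (0, 2)])
STAR5 = adjacency(5, [(0, i) for i in range(1, 5)])
PATH3 = adjacency(3, [(0, 1), (1, 2)])
K4 = adjacency(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


class TestSparsityGrid:
    def test_default_grid_has_37_levels(self):
        grid = SparsityGrid()
        assert len(grid) == 37
        assert grid.values[0] == pytest.approx(0.14)
        assert grid.values[-1] == pytest.approx(0.50)
        assert np.allclose(np.diff(grid.values), 0.01)

    @pytest.mark.parametrize("kwargs", [
        dict(k_min=0.5, k_max=0.2),
        dict(k_min=0.0),
        dict(k_max=1.0),
        dict(k_min=0.14, k_max=0.5, step=0.07),
    ])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SparsityGrid(**kwargs)


class TestBinarize:
    def test_hand_ranked_edges(self):
        w = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
                          (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.1}.items():
            w[i, j] = w[j, i] = v
        net = binarize(w, 0.5)
        assert net.n_edges == 3
        expected = adjacency(4, [(0, 1), (0, 2), (0, 3)])
        assert np.array_equal(net.adjacency, expected)

    def test_full_sparsity_keeps_everything(self):
        w = 0.5 * np.ones((5, 5))
        np.fill_diagonal(w, 1.0)
        net = binarize(w, 0.99)
        assert np.array_equal(net.adjacency,
                              np.ones((5, 5), dtype=np.int8) - np.eye(5, dtype=np.int8))

    def test_strong_negative_edge_retained_in_absolute_mode(self):
        w = np.full((5, 5), 0.1)
        np.fill_diagonal(w, 1.0)
        w[0, 1] = w[1, 0] = -0.95
        net = binarize(w, 0.14)
        assert net.adjacency[0, 1] == 1
        net_pos = binarize(w, 0.14, mode="positive")
        assert net_pos.adjacency[0, 1] == 0

    def test_edge_count_rounding(self):
        # 10 possible edges at n=5; K=0.45 -> round(4.5) away from zero = 5
        assert n_edges_at(0.45, 5) == 5
        assert binarize(np.random.default_rng(0).random((5, 5)), 0.45).n_edges == 5

    def test_zero_edges_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.eye(3), 0.01)

    def test_edge_sets_nested_along_grid(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(12, 12))
        w = (w + w.T) / 2
        grid = SparsityGrid(0.14, 0.5, 0.04)
        prev = None
        for k in grid.values:
            adj = binarize(w, float(k)).adjacency
            if prev is not None:
                assert np.all(adj >= prev)   # no previously connected pair lost
            prev = adj

    def test_tie_break_is_lexicographic(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 1.0)
        ii, jj = edge_ranking(w)
        assert list(zip(ii[:3], jj[:3])) == [(0, 1), (0, 2), (0, 3)]


class TestClosedFormGraphs:
    def test_triangle_fully_clustered(self):
        nodal, cp = clustering_coefficient(TRIANGLE)
        assert np.all(nodal == 1.0) and cp == 1.0

    def test_star_has_no_triangles(self):
        nodal, cp = clustering_coefficient(STAR5)
        assert cp == 0.0 and np.all(nodal == 0.0)

    def test_path_distances_and_length(self):
        d = shortest_path_lengths(PATH3)
        assert d[0, 2] == 2
        lp, _ = characteristic_path_length(PATH3)
        assert lp == pytest.approx(4 / 3)

    def test_disconnected_pairs_infinite_and_excluded(self):
        two_dyads = adjacency(4, [(0, 1), (2, 3)])
        d = shortest_path_lengths(two_dyads)
        assert np.isinf(d[0, 2])
        lp, nodal = characteristic_path_length(two_dyads)
        assert lp == 1.0           # only within-dyad pairs counted
        isolated = adjacency(3, [(0, 1)])
        lp2, nodal2 = characteristic_path_length(isolated)
        assert lp2 == 1.0 and nodal2[2] == 0.0

    def test_complete_graph_metrics(self):
        eg, _ = global_efficiency(K4)
        eloc, _ = local_efficiency(K4)
        lp, _ = characteristic_path_length(K4)
        _, btw = degree_and_betweenness(K4)
        assert eg == 1.0 and eloc == 1.0 and lp == 1.0
        assert np.all(btw == 0.0)

    def test_empty_graph_zero_efficiency(self):
        eg, _ = global_efficiency(np.zeros((4, 4)))
        assert eg == 0.0

    def test_star_local_efficiency_zero(self):
        eloc, _ = local_efficiency(STAR5)
        assert eloc == 0.0

    def test_star_hub_betweenness(self):
        deg, btw = degree_and_betweenness(STAR5)
        assert deg[0] == 4 and btw[0] == 6.0   # C(4,2) leaf pairs
        assert np.all(btw[1:] == 0.0)


class TestNetworkxCrossCheck:
    """Second independent route besides the brute-force oracles."""

    @pytest.mark.parametrize("seed", range(10))
    def test_metrics_match_networkx(self, seed):
        rng = np.random.default_rng(seed)
        a = random_graph(rng, 12, 0.3)
        g = nx.from_numpy_array(a)
        nodal_cp, cp = clustering_coefficient(a)
        assert np.allclose(nodal_cp, [nx.clustering(g)[i] for i in range(12)])
        deg, btw = degree_and_betweenness(a)
        nx_btw = nx.betweenness_centrality(g, normalized=False)
        assert np.allclose(btw, [nx_btw[i] for i in range(12)], atol=1e-10)
        eg, _ = global_efficiency(a)
        assert eg == pytest.approx(nx.global_efficiency(g), abs=1e-12)
        eloc, _ = local_efficiency(a)
        assert eloc == pytest.approx(nx.local_efficiency(g), abs=1e-12)


class TestConsistencyProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_global_equals_mean_of_nodal(self, seed):
        a = random_graph(np.random.default_rng(seed), 15, 0.25)
        nodal_cp, cp = clustering_coefficient(a)
        assert cp == pytest.approx(nodal_cp.mean(), abs=1e-12)
        eloc, nodal_el = local_efficiency(a)
        assert eloc == pytest.approx(nodal_el.mean(), abs=1e-12)

    def test_distances_match_floyd_warshall(self):
        for seed in range(10):
            a = random_graph(np.random.default_rng(seed), 10, 0.25)
            assert np.array_equal(shortest_path_lengths(a), floyd_warshall(a))


class TestSmallWorld:
    def test_zero_swaps_gives_sigma_one(self):
        a = random_graph(np.random.default_rng(0), 12, 0.3)
        res = small_world_index(a, n_random=3, seed=0, swap_factor=0)
        assert res.sigma == pytest.approx(1.0)

    def test_ring_lattice_is_small_world(self):
        n, k = 50, 2
        a = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for d in range(1, k + 1):
                a[i, (i + d) % n] = a[(i + d) % n, i] = 1
        res = small_world_index(a, n_random=20, seed=1)
        assert res.valid and res.sigma > 1.0

    def test_triangle_free_graph_flagged(self):
        res = small_world_index(STAR5, n_random=3, seed=0)
        assert not res.valid and np.isnan(res.sigma)

    def test_deterministic_for_fixed_seed(self):
        a = random_graph(np.random.default_rng(2), 20, 0.2)
        r1 = small_world_index(a, n_random=10, seed=42)
        r2 = small_world_index(a, n_random=10, seed=42)
        assert r1.sigma == r2.sigma

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            small_world_index(np.zeros((4, 4)), n_random=2, seed=0)


class TestGridValidation:
    def test_dense_positive_matrices_stay_connected(self):
        rng = np.random.default_rng(0)
        mats = [np.corrcoef(rng.normal(size=(30, 10)), rowvar=False) + 0.5
                for _ in range(3)]
        grid = SparsityGrid(0.3, 0.5, 0.1)
        report = validate_sparsity_grid(mats, grid, n_random=3, seed=0)
        assert len(report) == len(grid)
        assert (report["frac_connected"] == 1.0).all()

    def test_fragmented_networks_flagged(self):
        # two 5-cliques, no bridge: largest component is half the nodes
        w = np.zeros((10, 10))
        w[:5, :5] = 0.9
        w[5:, 5:] = 0.9
        np.fill_diagonal(w, 1.0)
        grid = SparsityGrid(0.2, 0.3, 0.1)
        report = validate_sparsity_grid([w] * 2, grid, n_random=2, seed=0)
        assert (report["frac_connected"] == 0.0).all()
        assert report["flagged"].all()


class TestAUC:
    def test_constant_curve_closed_form(self):
        grid = SparsityGrid()
        assert auc(np.full(37, 2.0), grid) == pytest.approx(0.72, abs=1e-12)

    def test_linear_curve_closed_form(self):
        grid = SparsityGrid()
        assert auc(np.linspace(0, 1, 37), grid) == pytest.approx(0.18, abs=1e-12)

    def test_matches_manual_trapezoid(self):
        rng = np.random.default_rng(5)
        grid = SparsityGrid()
        vals = rng.random(37)
        assert auc(vals, grid) == pytest.approx(
            trapezoid_sum(vals, grid.values), abs=1e-12)

    def test_nodal_curves_integrated_per_node(self):
        grid = SparsityGrid(0.2, 0.4, 0.1)
        vals = np.tile(np.array([1.0, 2.0]), (3, 1))
        out = auc(vals, grid)
        assert np.allclose(out, [0.2, 0.4])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            auc(np.ones(5), SparsityGrid())


class TestMetricCurves:
    def test_curve_lengths_and_plausible_auc_scale(self, small_cohort):
        from scnkit import (build_group_scn, build_individual_scns,
                            control_reference, residualize)
        cohort, _ = small_cohort
        res, coef = residualize(cohort)
        ctrl = res.subset(cohort.group_mask("control"))
        gscn = build_group_scn(ctrl)
        ref = control_reference(ctrl, coef)
        scn = build_individual_scns(res, ref, gscn, cohort.subject_ids[:1])[0]
        grid = SparsityGrid()
        curves = metric_curves(scn.matrix, grid,
                               metrics=("Cp", "Lp", "Eg", "Eloc", "degree"))
        assert curves["Cp"].shape == (37,)
        assert curves["degree"].shape == (37, 16)
        cp_auc = auc(curves["Cp"], grid)
        lp_auc = auc(curves["Lp"], grid)
        assert 0.0 < cp_auc < 0.36          # Cp in [0, 1] over a 0.36-wide grid
        assert 0.36 < lp_auc < 3.6          # Lp in (1, 10) on near-connected nets
        # density rises with K, so degree curves are non-decreasing
        assert np.all(np.diff(curves["degree"], axis=0) >= 0)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            metric_curves(np.eye(4), SparsityGrid(), metrics=("Qmax",))


def test_brute_force_oracles_agree_on_closed_forms():
    """Sanity of the oracles themselves on hand-checked graphs."""
    assert brute_clustering(TRIANGLE)[1] == 1.0
    assert brute_path_length(PATH3)[0] == pytest.approx(4 / 3)
    assert brute_global_efficiency(K4)[0] == 1.0
    assert brute_local_efficiency(STAR5)[0] == 0.0
    assert brute_betweenness(STAR5)[0] == 6.0
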