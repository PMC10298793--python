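import networkx as nx
import numpy as np
import pytest

from slnet.graph_metrics import (
    AdjacencyMatrix,
    binarize_by_density,
    binarize_by_threshold,
    characteristic_path_length,
    clustering_coefficient,
    compute_metrics,
    er_null_ensemble,
    global_efficiency,
    nodal_efficiency,
    small_worldness,
)
from slnet.synthetic import make_graph_fixture

from _oracles import (
    oracle_clustering,
    oracle_global_efficiency,
    oracle_nodal_efficiency,
    oracle_path_length,
)

KITE4 = AdjacencyMatrix(np.array([
    [0, 1, 1, 0],
    [1, 0, 1, 0],
    [1, 1, 0, 1],
    [0, 0, 1, 0],
]))


class TestBinarize:
    def test_full_density_gives_complete_graph(self, rng):
        sl = rng.random((6, 6))
        sl = (sl + sl.T) / 2
        adj = binarize_by_density(sl, 1.0)
        assert adj.n_edges == 15

    def test_density_02_on_19_nodes_gives_34_edges(self, rng):
        sl = rng.random((19, 19))
        sl = (sl + sl.T) / 2
        adj = binarize_by_density(sl, 0.2)
        assert adj.n_edges == 34  # floor(0.2 * 171)

    def test_nested_thresholds(self, rng):
        sl = rng.random((12, 12))
        sl = (sl + sl.T) / 2
        low = binarize_by_density(sl, 0.15)
        high = binarize_by_density(sl, 0.4)
        assert np.all(high.a[low.a == 1] == 1)

    def test_keeps_strongest_pairs(self):
        sl = np.zeros((4, 4))
        sl[0, 1] = sl[1, 0] = 0.9
        sl[2, 3] = sl[3, 2] = 0.8
        sl[0, 2] = sl[2, 0] = 0.1
        adj = binarize_by_density(sl, 2 / 6)
        assert adj.a[0, 1] == 1 and adj.a[2, 3] == 1 and adj.a[0, 2] == 0

    def test_tie_break_is_deterministic(self):
        sl = np.full((4, 4), 0.5)
        np.fill_diagonal(sl, 0)
        adj = binarize_by_density(sl, 1 / 6)
        assert adj.a[0, 1] == 1 and adj.n_edges == 1

    def test_zero_edge_density_rejected(self, rng):
        sl = rng.random((5, 5))
        with pytest.raises(ValueError, match="zero edges"):
            binarize_by_density((sl + sl.T) / 2, 0.01)

    def test_threshold_mode(self):
        sl = np.array([[0, 0.9, 0.1], [0.9, 0, 0.2], [0.1, 0.2, 0]])
        adj = binarize_by_threshold(sl, 0.5)
        assert adj.n_edges == 1 and adj.a[0, 1] == 1


class TestClosedForms:
    def test_complete_graph_L_is_one(self):
        L, connected = characteristic_path_length(make_graph_fixture("complete", n=7))
        assert L == 1.0 and connected

    def test_path3_L(self):
        L, _ = characteristic_path_length(make_graph_fixture("path", n=3))
        assert L == pytest.approx(4 / 3)

    def test_star_L(self):
        L, _ = characteristic_path_length(make_graph_fixture("star", n=4))
        assert L == pytest.approx(1.5)

    def test_complete_clustering_one(self):
        _, c = clustering_coefficient(make_graph_fixture("complete", n=4))
        assert c == 1.0

    def test_star_clustering_zero(self):
        _, c = clustering_coefficient(make_graph_fixture("star", n=5))
        assert c == 0.0

    def test_kite_clustering(self):
        ci, c = clustering_coefficient(KITE4)
        assert c == pytest.approx(7 / 12)
        np.testing.assert_allclose(ci, [1.0, 1.0, 1 / 3, 0.0])

    def test_complete_Eg_one(self):
        assert global_efficiency(make_graph_fixture("complete", n=19)) == 1.0

    def test_edgeless_Eg_zero(self):
        assert global_efficiency(AdjacencyMatrix(np.zeros((5, 5)))) == 0.0

    def test_path3_Eg(self):
        assert global_efficiency(make_graph_fixture("path", n=3)) == pytest.approx(5 / 6)

    def test_complete_El_global_sum_is_1_over_n(self):
        el = nodal_efficiency(make_graph_fixture("complete", n=19), "global_sum")
        np.testing.assert_allclose(el, np.full(19, 1 / 19))

    def test_complete_El_per_node_is_one(self):
        el = nodal_efficiency(make_graph_fixture("complete", n=8), "per_node")
        np.testing.assert_allclose(el, np.ones(8))

    def test_isolated_node_El_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1
        el = nodal_efficiency(AdjacencyMatrix(a), "per_node")
        assert el[2] == 0.0 and el[3] == 0.0

    def test_edgeless_L_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            characteristic_path_length(AdjacencyMatrix(np.zeros((4, 4))))

    def test_disconnected_graph_flagged(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        L, connected = characteristic_path_length(AdjacencyMatrix(a))
        assert L == 1.0 and not connected


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(50))
    def test_random_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        p = float(rng.uniform(0.15, 0.8))
        adj = make_graph_fixture("er", n=n, p=p, seed=seed)
        a = adj.a
        if a.sum() == 0:
            return
        L, _ = characteristic_path_length(adj)
        assert L == pytest.approx(oracle_path_length(a), abs=1e-12)
        ci, c = clustering_coefficient(adj)
        oci, oc = oracle_clustering(a)
        np.testing.assert_allclose(ci, oci, atol=1e-12)
        assert c == pytest.approx(oc, abs=1e-12)
        assert global_efficiency(adj) == pytest.approx(
            oracle_global_efficiency(a), abs=1e-12)
        np.testing.assert_allclose(
            nodal_efficiency(adj, "per_node"), oracle_nodal_efficiency(a),
            atol=1e-12)

    def test_matches_networkx_on_connected_graph(self):
        adj = make_graph_fixture("small_world", n=40, k=4, p=0.2, seed=3)
        g = nx.from_numpy_array(adj.a)
        if not nx.is_connected(g):
            g = g.subgraph(max(nx.connected_components(g), key=len))
            adj = AdjacencyMatrix(nx.to_numpy_array(g, nodelist=sorted(g)))
            g = nx.from_numpy_array(adj.a)
        L, _ = characteristic_path_length(adj)
        assert L == pytest.approx(nx.average_shortest_path_length(g))
        _, c = clustering_coefficient(adj)
        assert c == pytest.approx(nx.average_clustering(g))
        assert global_efficiency(adj) == pytest.approx(nx.global_efficiency(g))


class TestInvariants:
    def test_el_sums_to_eg(self, rng):
        for seed in range(10):
            adj = make_graph_fixture("er", n=15, p=0.3, seed=seed)
            if adj.n_edges == 0:
                continue
            el = nodal_efficiency(adj, "global_sum")
            assert el.sum() == pytest.approx(global_efficiency(adj), abs=1e-12)

    def test_eg_monotone_in_density(self, rng):
        sl = rng.random((19, 19))
        sl = (sl + sl.T) / 2
        egs = [global_efficiency(binarize_by_density(sl, q))
               for q in (0.1, 0.2, 0.4, 0.7, 1.0)]
        assert all(b >= a for a, b in zip(egs, egs[1:]))


class TestNullEnsemble:
    def test_p1_exact(self):
        null = er_null_ensemble(10, 1.0, 5, seed=0)
        assert null.c_rand == 1.0 and null.l_rand == 1.0

    def test_expected_edge_count(self):
        n, p = 19, 0.3
        rngsum = 0
        reps = 200
        rng = np.random.default_rng(0)
        for s in range(reps):
            a = make_graph_fixture("er", n=n, p=p, seed=int(rng.integers(2**31)))
            rngsum += a.n_edges
        expected = p * n * (n - 1) / 2
        assert rngsum / reps == pytest.approx(expected, rel=0.05)

    def test_seeded_reproducibility(self):
        a = er_null_ensemble(19, 0.3, 50, seed=42)
        b = er_null_ensemble(19, 0.3, 50, seed=42)
        assert a.c_rand == b.c_rand and a.l_rand == b.l_rand

    def test_tiny_p_all_edgeless_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            er_null_ensemble(5, 1e-9, 20, seed=0)


class TestSmallWorldness:
    def test_self_null_gives_one(self):
        adj = make_graph_fixture("er", n=19, p=0.3, seed=1)
        L, _ = characteristic_path_length(adj)
        _, c = clustering_coefficient(adj)
        from slnet.graph_metrics import NullEnsembleSummary

        null = NullEnsembleSummary(c_rand=c, l_rand=L, n_realizations=1, p=0.3)
        assert small_worldness((L, c), null) == pytest.approx(1.0)

    def test_rewired_lattice_exceeds_one(self):
        adj = make_graph_fixture("small_world", n=100, k=6, p=0.1, seed=0)
        gm = compute_metrics(adj, null_realizations=100, seed=1)
        assert gm.SWN > 1.2

    def test_degenerate_null_rejected(self):
        from slnet.graph_metrics import NullEnsembleSummary

        null = NullEnsembleSummary(c_rand=0.0, l_rand=1.5, n_realizations=1, p=0.1)
        with pytest.raises(ValueError, match="degenerate"):
            small_worldness((1.5, 0.3), null)

    def test_compute_metrics_bundle(self):
        adj = make_graph_fixture("er", n=19, p=0.4, seed=7)
        gm = compute_metrics(adj, null_realizations=50, seed=2)
        assert gm.L >= 1.0
        assert 0.0 <= gm.C <= 1.0
        assert 0.0 <= gm.Eg <= 1.0
        assert gm.El.shape == (19,)
        assert gm.null_summary.p == pytest.approx(adj.density)
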