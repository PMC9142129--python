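"""Ensemble over variable orders: aggregation, selection, diagnostics."""

import numpy as np
import pytest

from spcanet import SimulationSpec, simulate_dataset
from spcanet.pcapmi import PruneConfig, run_pcapmi
from spcanet.spca import (
    EdgeScoreTable,
    EnsembleResult,
    aggregate,
    check_threshold_guidance,
    edge_frequency_histogram,
    mst_completion,
    run_ensemble,
    sample_orders,
    select_top_m,
    variation_ratio,
)


def manual_ensemble(weights, scores):
    """Build an EnsembleResult from explicit per-run matrices."""
    w = np.asarray(weights, dtype=np.int8)
    s = np.asarray(scores, dtype=float)
    N, n, _ = w.shape
    counts = np.array([np.triu(w[k], 1).sum() for k in range(N)])
    orders = tuple(tuple(range(n)) for _ in range(N))
    return EnsembleResult(orders, w, s, counts)


def sym(n, entries):
    m = np.zeros((n, n))
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return m


class TestSampleOrders:
    def test_valid_permutations_and_determinism(self):
        a = sample_orders(3, 6, seed=4)
        b = sample_orders(3, 6, seed=4)
        assert a == b
        assert all(sorted(p) == [0, 1, 2] for p in a)

    def test_uniform_over_permutations(self):
        """Empirical frequency of each order within 3 SE of uniform."""
        N = 10_000
        orders = sample_orders(5, N, seed=1)
        from collections import Counter

        counts = Counter(orders)
        assert len(counts) == 120
        p = 1 / 120
        se = (N * p * (1 - p)) ** 0.5
        for c in counts.values():
            assert abs(c - N * p) <= 3 * se + 1


class TestRunEnsemble:
    def test_single_run_matches_pcapmi(self, fixture_instance):
        D, _ = fixture_instance
        cfg = PruneConfig(epsilon=0.05, max_order=2)
        ens = run_ensemble(D, cfg, N=1, seed=5)
        direct = run_pcapmi(
            D, PruneConfig(epsilon=0.05, max_order=2, order=ens.orders[0])
        )
        assert np.array_equal(ens.weights[0], direct.adjacency)
        assert ens.edge_counts[0] == direct.n_edges

    def test_tiny_threshold_gives_complete_graphs(self, fixture_instance):
        D, _ = fixture_instance
        ens = run_ensemble(D, PruneConfig(epsilon=1e-12, max_order=1), N=5, seed=0)
        assert np.all(ens.edge_counts == 10)

    def test_order_dependence_manifests_in_edge_counts(self):
        D, _ = simulate_dataset(SimulationSpec(n=20, m=100, density=0.12, seed=21))
        ens = run_ensemble(D, PruneConfig(epsilon=0.03, max_order=2), N=50, seed=3)
        assert len(set(ens.edge_counts.tolist())) > 1
        assert variation_ratio(ens.edge_counts) > 0

    def test_reproducibility_is_bit_identical(self, fixture_instance):
        D, _ = fixture_instance
        cfg = PruneConfig(epsilon=0.05)
        e1 = run_ensemble(D, cfg, N=10, seed=9)
        e2 = run_ensemble(D, cfg, N=10, seed=9)
        t1, t2 = aggregate(e1), aggregate(e2)
        for a, b in ((t1.mw, t2.mw), (t1.apmi, t2.apmi), (t1.mpmi, t2.mpmi)):
            assert np.array_equal(a, b)


class TestAggregate:
    def test_worked_arithmetic(self):
        """Edge present in 3 of 4 runs with scores (.2, .4, .3) and a failing
        .1 in the run that removed it."""
        n, N = 3, 4
        w = [sym(n, {(0, 1): 1})] * 3 + [sym(n, {})]
        s = [
            sym(n, {(0, 1): 0.2}),
            sym(n, {(0, 1): 0.4}),
            sym(n, {(0, 1): 0.3}),
            sym(n, {(0, 1): 0.1}),
        ]
        table = aggregate(manual_ensemble(w, s))
        assert table.mw[0, 1] == pytest.approx(0.75)
        assert table.apmi[0, 1] == pytest.approx(0.225)
        assert table.mpmi[0, 1] == pytest.approx(0.4)
        assert table.case[0, 1] == 2

    def test_case_boundaries(self):
        n = 3
        w = [sym(n, {(0, 1): 1}), sym(n, {(0, 1): 1})]
        s = [sym(n, {(0, 1): 0.5, (0, 2): 0.01}), sym(n, {(0, 1): 0.6, (0, 2): 0.02})]
        table = aggregate(manual_ensemble(w, s))
        assert table.case[0, 1] == 1 and table.mw[0, 1] == 1.0
        assert table.case[0, 2] == 3 and table.mw[0, 2] == 0.0
        assert table.apmi[0, 2] == 0.0
        assert table.mpmi[0, 2] == pytest.approx(0.02)  # failing scores kept

    def test_absent_scores_zero_mode(self):
        n = 3
        w = [sym(n, {(0, 1): 1}), sym(n, {})]
        s = [sym(n, {(0, 1): 0.5}), sym(n, {(0, 1): 0.9})]
        table = aggregate(manual_ensemble(w, s), absent_scores="zero")
        assert table.mpmi[0, 1] == pytest.approx(0.5)

    def test_mpmi_dominates_apmi(self):
        D, _ = simulate_dataset(SimulationSpec(n=15, m=100, density=0.1, seed=2))
        table = aggregate(run_ensemble(D, PruneConfig(epsilon=0.03), N=20, seed=1))
        iu = np.triu_indices(15, 1)
        assert np.all(table.mpmi[iu] >= table.apmi[iu] - 1e-12)


class TestSelection:
    @pytest.fixture
    def toy_table(self):
        n = 4
        mw = sym(n, {(0, 1): 0.9, (0, 2): 0.5, (1, 2): 0.5, (2, 3): 0.1})
        case = np.full((n, n), 2)
        np.fill_diagonal(case, 0)
        return EdgeScoreTable(mw, mw * 0.1, mw * 0.2, case)

    def test_all_pairs_when_m_is_total(self, toy_table):
        assert len(select_top_m(toy_table, "MW", 6)) == 6

    def test_deterministic_tie_break(self, toy_table):
        top = select_top_m(toy_table, "MW", 2)
        assert top[0][:2] == (0, 1)
        assert top[1][:2] == (0, 2)  # (0,2) beats (1,2) on index order

    @pytest.mark.parametrize("M", [0, 7])
    def test_m_out_of_range(self, toy_table, M):
        with pytest.raises(ValueError):
            select_top_m(toy_table, "MW", M)

    def test_case1_edges_always_selected_under_mw(self):
        D, _ = simulate_dataset(SimulationSpec(n=15, m=150, density=0.1, seed=8))
        table = aggregate(run_ensemble(D, PruneConfig(epsilon=0.03), N=20, seed=2))
        iu = np.triu_indices(15, 1)
        n_case1 = int((table.case[iu] == 1).sum())
        if n_case1 == 0:
            pytest.skip("instance produced no Case-1 edges")
        top = {e[:2] for e in select_top_m(table, "MW", n_case1)}
        case1 = {
            (i, j)
            for i, j in zip(*iu)
            if table.case[i, j] == 1
        }
        assert case1 == top


class TestVariationRatio:
    def test_constant_counts(self):
        assert variation_ratio([7, 7, 7]) == 0.0

    def test_published_style_worked_rows(self):
        # count vectors realising (min, max, mean) = (95, 113, 105) and (136, 161, 155)
        assert variation_ratio([95, 113, 107]) == pytest.approx(18 / 105)
        assert variation_ratio([136, 161, 161, 161, 156]) == pytest.approx(25 / 155)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            variation_ratio([0, 0])


class TestMstCompletion:
    def test_spanning_tree_when_m_is_minimal(self):
        n = 4
        rng = np.random.default_rng(0)
        sc = rng.uniform(0.1, 1.0, size=(n, n))
        sc = (sc + sc.T) / 2
        np.fill_diagonal(sc, 0)
        table = EdgeScoreTable(sc, sc, sc, np.full((n, n), 2))
        out = mst_completion(table, "MPMI", 3)
        assert len(out) == 3
        import networkx as nx

        g = nx.Graph([(i, j) for i, j, _ in out])
        assert nx.is_connected(g) and g.number_of_nodes() == 4

    def test_reconnects_a_disconnected_top_m(self):
        """Two tight cliques: top-M picks only intra-clique edges, MST
        completion bridges them."""
        n = 6
        entries = {}
        for grp in ((0, 1, 2), (3, 4, 5)):
            for a in grp:
                for b in grp:
                    if a < b:
                        entries[(a, b)] = 0.9
        entries[(2, 3)] = 0.1  # the only worthwhile bridge
        sc = sym(n, entries)
        table = EdgeScoreTable(sc, sc, sc, np.full((n, n), 2))
        import networkx as nx

        top = select_top_m(table, "MW", 6)
        g_top = nx.Graph([(i, j) for i, j, _ in top])
        g_top.add_nodes_from(range(n))
        assert not nx.is_connected(g_top)
        out = mst_completion(table, "MW", 6)
        g = nx.Graph([(i, j) for i, j, _ in out])
        g.add_nodes_from(range(n))
        assert nx.is_connected(g)
        assert (2, 3) in {e[:2] for e in out}

    def test_equal_scores_still_connect(self):
        n = 5
        sc = np.ones((n, n)) * 0.5
        np.fill_diagonal(sc, 0)
        table = EdgeScoreTable(sc, sc, sc, np.full((n, n), 2))
        import networkx as nx

        out = mst_completion(table, "APMI", 4)
        assert nx.is_connected(nx.Graph([(i, j) for i, j, _ in out]))

    def test_too_small_m_rejected(self):
        n = 4
        sc = np.zeros((n, n))
        table = EdgeScoreTable(sc, sc, sc, np.full((n, n), 2))
        with pytest.raises(ValueError):
            mst_completion(table, "MW", 2)


class TestDiagnostics:
    def test_histogram_conserves_case2_count(self):
        D, _ = simulate_dataset(SimulationSpec(n=15, m=100, density=0.1, seed=3))
        table = aggregate(run_ensemble(D, PruneConfig(epsilon=0.03), N=30, seed=4))
        counts, edges = edge_frequency_histogram(table, bins=7)
        iu = np.triu_indices(15, 1)
        assert counts.sum() == int((table.case[iu] == 2).sum())
        assert len(counts) == 7

    def test_histogram_empty_without_case2(self):
        n = 3
        case = np.full((n, n), 3)
        z = np.zeros((n, n))
        counts, _ = edge_frequency_histogram(EdgeScoreTable(z, z, z, case), bins=5)
        assert counts.sum() == 0

    def test_threshold_guidance_warning(self):
        n = 4
        case = np.full((n, n), 1)  # every pair Case 1
        np.fill_diagonal(case, 0)
        z = np.zeros((n, n))
        table = EdgeScoreTable(z, z, z, case)
        with pytest.warns(UserWarning, match="threshold guidance"):
            assert not check_threshold_guidance(table, expected_edges=3)
        case2 = np.full((n, n), 2)
        np.fill_diagonal(case2, 0)
        table2 = EdgeScoreTable(z, z, z, case2)
        assert check_threshold_guidance(table2, expected_edges=3)
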