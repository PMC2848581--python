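"""Network growth policy and topology diagnostics."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardionet import (
    DataError,
    FitError,
    InteractionDB,
    average_degree,
    clustering_coefficients,
    degree_histogram,
    grow_network,
    hierarchy_fit,
    scale_free_fit,
)
from _oracles import clustering as oracle_clustering, degree_histogram as oracle_hist


def db_from_edges(edges, extra_nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return InteractionDB(graph=g)


class TestGrowNetwork:
    def test_all_nodes_as_seeds_returns_whole_graph(self):
        db = db_from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        net = grow_network(["a", "b", "c"], db)
        assert set(net.graph.nodes) == {"a", "b", "c"}
        assert net.n_edges == 3

    def test_partner_with_two_seed_links_is_admitted(self):
        db = db_from_edges([("s1", "p"), ("s2", "p")])
        net = grow_network(["s1", "s2"], db)
        assert "p" in net.graph

    def test_partner_with_one_seed_link_is_excluded_by_default(self):
        db = db_from_edges([("s1", "p"), ("p", "q")])
        net = grow_network(["s1"], db)
        assert set(net.graph.nodes) == {"s1"}
        net1 = grow_network(["s1"], db, min_seed_links=1)
        assert set(net1.graph.nodes) == {"s1", "p"}

    def test_isolated_seeds_give_zero_edges(self):
        db = db_from_edges([("x", "y")], extra_nodes=["s1", "s2"])
        net = grow_network(["s1", "s2"], db)
        assert net.n_edges == 0
        assert set(net.graph.nodes) == {"s1", "s2"}

    def test_no_seed_in_db_is_error(self):
        db = db_from_edges([("a", "b")])
        with pytest.raises(DataError, match="missing"):
            grow_network(["zz"], db)

    def test_seed_order_invariance(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(30, 0.15, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(30)})
        db = InteractionDB(graph=g)
        seeds = [f"n{i}" for i in range(0, 30, 3)]
        nets = [
            grow_network(perm, db)
            for perm in (seeds, seeds[::-1], list(rng.permutation(seeds)))
        ]
        edge_sets = [frozenset(map(frozenset, n.graph.edges)) for n in nets]
        assert edge_sets[0] == edge_sets[1] == edge_sets[2]


class TestDegreeHistogram:
    def test_path_of_three(self):
        g = nx.path_graph(3)
        n_k, p_k = degree_histogram(g)
        assert n_k == {1: 2, 2: 1}
        assert p_k[1] == pytest.approx(2 / 3)

    def test_complete_graph(self):
        n_k, p_k = degree_histogram(nx.complete_graph(5))
        assert n_k == {4: 5}
        assert p_k == {4: 1.0}

    def test_isolated_nodes_get_k0_bin(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        n_k, p_k = degree_histogram(g)
        assert n_k[0] == 1

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_and_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 26))
        g = nx.gnp_random_graph(n, 0.3, seed=seed)
        n_k, p_k = degree_histogram(g)
        assert n_k == oracle_hist(list(g.nodes), list(g.edges))
        assert sum(n_k.values()) == n
        assert sum(p_k.values()) == pytest.approx(1.0)


class TestClustering:
    def test_triangle_all_ones(self):
        c_i, c_k = clustering_coefficients(nx.complete_graph(3))
        assert all(v == 1.0 for v in c_i.values())
        assert c_k == {2: 1.0}

    def test_star_center_zero(self):
        c_i, _ = clustering_coefficients(nx.star_graph(4))
        assert c_i[0] == 0.0

    def test_low_degree_nodes_excluded_from_bins_by_default(self):
        g = nx.path_graph(2)
        _, c_k = clustering_coefficients(g)
        assert c_k == {}
        _, c_k_incl = clustering_coefficients(g, exclude_low_degree=False)
        assert c_k_incl == {1: 0.0}

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_triangle_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 26))
        g = nx.gnp_random_graph(n, 0.35, seed=seed + 1)
        c_i, _ = clustering_coefficients(g)
        expected = oracle_clustering(list(g.nodes), list(g.edges))
        assert c_i.keys() == expected.keys()
        for node in expected:
            assert c_i[node] == pytest.approx(expected[node], abs=1e-12)


class TestFits:
    def test_exact_power_law(self):
        k = np.arange(1, 11)
        p_k = {int(kk): float(0.2 * kk**-3.0) for kk in k}
        slope, r = scale_free_fit(p_k)
        assert slope == pytest.approx(-3.0, abs=1e-9)
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_two_bins_is_fit_error(self):
        with pytest.raises(FitError):
            scale_free_fit({1: 0.5, 2: 0.5})

    def test_zero_mass_bins_dropped(self):
        # exact 0.4 * k**-3 at k = 1, 2, 4, 8 with a zero-mass bin at 3
        p_k = {1: 0.4, 2: 0.05, 3: 0.0, 4: 0.00625, 8: 0.00078125}
        slope, r = scale_free_fit(p_k)
        assert slope == pytest.approx(-3.0, abs=1e-9)

    def test_hierarchy_inverse_k(self):
        c_k = {k: 1.0 / k for k in range(1, 8)}
        slope, r = hierarchy_fit(c_k)
        assert slope == pytest.approx(-1.0, abs=1e-9)
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_hierarchy_constant_slope_zero(self):
        c_k = {k: 0.25 for k in range(1, 6)}
        slope, _ = hierarchy_fit(c_k)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_triad_closure_graph_has_negative_hierarchy_slope(self):
        from cardionet import preferential_attachment_graph

        g = preferential_attachment_graph(600, m=4, triad_p=0.4, seed=0)
        _, c_k = clustering_coefficients(g)
        slope, r = hierarchy_fit(c_k)
        assert slope < 0
        assert abs(r) > 0.5


class TestAverageDegree:
    def test_complete_graph(self):
        avg, mean_nb = average_degree(nx.complete_graph(5))
        assert avg == 4.0
        assert mean_nb == 4.0

    def test_forced_arithmetic_at_reported_scale(self):
        g = nx.gnm_random_graph(363, 1801, seed=0)
        avg, _ = average_degree(g)
        assert avg == pytest.approx(2 * 1801 / 363)
        assert avg == pytest.approx(9.92, abs=0.005)

    def test_empty_graph(self):
        g = nx.empty_graph(10)
        avg, mean_nb = average_degree(g)
        assert avg == 0.0
        assert mean_nb == 0.0


def test_scale_free_fit_discriminates_pa_from_er():
    """The log-log degree fit is markedly more linear on a
    preferential-attachment graph than on a density-matched random graph."""
    from cardionet import preferential_attachment_graph

    pa = preferential_attachment_graph(800, seed=3)
    er = nx.gnm_random_graph(800, pa.number_of_edges(), seed=3)
    _, p_pa = degree_histogram(pa)
    _, p_er = degree_histogram(er)
    s_pa, r_pa = scale_free_fit(p_pa)
    _, r_er = scale_free_fit(p_er)
    assert s_pa < 0
    assert abs(r_pa) > abs(r_er)
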