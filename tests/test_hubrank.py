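"""Hub identification, connectivity scoring and the minimal axis cover."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardionet import (
    Axis,
    DataError,
    HubSet,
    identify_hubs,
    local_module_connectivity,
    minimal_axis_cover,
    relative_connectivity_score,
)
from _oracles import degree_counts, hub_adjacency_counts, min_cover_size


class TestLocalModuleConnectivity:
    def test_complete_graph(self):
        conn = local_module_connectivity(nx.complete_graph(4))
        assert set(conn.values()) == {3}

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("x")
        assert local_module_connectivity(g) == {"x": 0}

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_degree_oracle(self, seed):
        g = nx.gnp_random_graph(int(np.random.default_rng(seed).integers(2, 26)), 0.3, seed=seed)
        assert local_module_connectivity(g) == degree_counts(list(g.nodes), list(g.edges))


class TestIdentifyHubs:
    def test_star_center_selected(self):
        hubs = identify_hubs(nx.star_graph(5), n_hubs=1)
        assert hubs.hubs == (0,)
        assert not hubs.tie_expanded

    def test_cycle_all_tied_expands(self):
        hubs = identify_hubs(nx.cycle_graph(6), n_hubs=1)
        assert len(hubs) == 6
        assert hubs.tie_expanded

    def test_connectivity_sorted_descending(self):
        g = nx.Graph([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])
        hubs = identify_hubs(g, n_hubs=2)
        values = list(hubs.connectivity.values())
        assert values == sorted(values, reverse=True)

    def test_min_connectivity_rule(self):
        g = nx.star_graph(4)
        hubs = identify_hubs(g, min_connectivity=2)
        assert hubs.hubs == (0,)

    def test_empty_network_is_error(self):
        with pytest.raises(DataError):
            identify_hubs(nx.Graph(), n_hubs=1)

    def test_permutation_invariance(self):
        edges = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("d", "e")]
        g1 = nx.Graph(edges)
        g2 = nx.Graph(edges[::-1])
        assert identify_hubs(g1, n_hubs=2).hubs == identify_hubs(g2, n_hubs=2).hubs

    def test_planted_hubs_recovered_across_seeds(self, small_config):
        """The generator's nine planted hubs are exactly the top-degree
        nodes of the grown sub-network."""
        from cardionet import SynthConfig, generate_expression, generate_interactions, grow_network
        import dataclasses

        for seed in range(5):
            config = dataclasses.replace(small_config, seed=seed)
            _, _, truth = generate_expression(config)
            db = generate_interactions(config, truth)
            net = grow_network(truth.conserved, db)
            hubs = identify_hubs(net, n_hubs=config.n_hubs)
            assert set(hubs.hubs) == set(truth.planted_hubs)


class TestRelativeConnectivityScore:
    def test_full_and_partial_adjacency(self):
        g = nx.Graph()
        hubs_nodes = [f"h{i}" for i in range(9)]
        for h in hubs_nodes:
            g.add_edge("gene_all", h)
        for h in hubs_nodes[:3]:
            g.add_edge("gene_three", h)
        g.add_edge("other", "gene_all")
        hubs = HubSet(
            hubs=tuple(hubs_nodes),
            connectivity={h: g.degree(h) for h in hubs_nodes},
            rule="top-9",
        )
        table = relative_connectivity_score(["gene_all", "gene_three"], hubs, g)
        assert table.loc["gene_all", "Y"] == 1.0
        assert table.loc["gene_three", "Y"] == pytest.approx(1 / 3)

    def test_absent_gene_scores_zero(self):
        g = nx.Graph([("h", "x")])
        hubs = HubSet(hubs=("h",), connectivity={"h": 1}, rule="top-1")
        table = relative_connectivity_score(["ghost"], hubs, g)
        assert table.loc["ghost", "Y"] == 0.0

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_adjacency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(15, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(15)})
        hub_names = [f"n{i}" for i in rng.choice(15, size=4, replace=False)]
        hubs = HubSet(
            hubs=tuple(hub_names),
            connectivity={h: g.degree(h) for h in hub_names},
            rule="top-4",
        )
        genes = [f"n{i}" for i in range(15) if f"n{i}" not in hub_names]
        table = relative_connectivity_score(genes, hubs, g)
        expected = hub_adjacency_counts(genes, hub_names, list(g.edges))
        for gene in genes:
            assert table.loc[gene, "x"] == expected[gene]
            assert table.loc[gene, "Y"] == pytest.approx(expected[gene] / 4)

    def test_monotone_in_added_hub_edges(self):
        g = nx.Graph([("gene", "h0"), ("h1", "x"), ("h2", "x")])
        hubs = HubSet(
            hubs=("h0", "h1", "h2"),
            connectivity={"h0": 1, "h1": 1, "h2": 1},
            rule="top-3",
        )
        y0 = relative_connectivity_score(["gene"], hubs, g).loc["gene", "Y"]
        g.add_edge("gene", "h1")
        y1 = relative_connectivity_score(["gene"], hubs, g).loc["gene", "Y"]
        assert y1 > y0


def make_cover_instance(hit_map, hubs_n):
    """Build a star-like graph realizing receptor->hub adjacencies."""
    g = nx.Graph()
    hub_names = [f"h{i}" for i in range(hubs_n)]
    g.add_nodes_from(hub_names)
    axes = []
    for i, hit in enumerate(hit_map):
        receptor = f"r{i}"
        g.add_node(receptor)
        for h in hit:
            g.add_edge(receptor, hub_names[h])
        axes.append(Axis(ligand=f"l{i}", receptor=receptor, name=f"axis{i:02d}"))
    hubs = HubSet(
        hubs=tuple(hub_names),
        connectivity={h: max(g.degree(h), 1) for h in hub_names},
        rule=f"top-{hubs_n}",
    )
    return g, axes, hubs


class TestMinimalAxisCover:
    def test_single_axis_covering_everything(self):
        g, axes, hubs = make_cover_instance([{0, 1, 2}], 3)
        cover = minimal_axis_cover(axes, hubs, g)
        assert cover.size == 1 and cover.feasible and cover.minimal

    def test_empty_hub_set_is_vacuously_feasible(self):
        g, axes, _ = make_cover_instance([{0}], 1)
        empty = HubSet(hubs=(), connectivity={}, rule="top-0")
        cover = minimal_axis_cover(axes, empty, g)
        assert cover.size == 0 and cover.feasible

    def test_infeasible_returns_partial_with_uncovered(self):
        g, axes, hubs = make_cover_instance([{0}, {1}], 3)
        cover = minimal_axis_cover(axes, hubs, g)
        assert not cover.feasible
        assert cover.uncovered == {"h2"}
        assert cover.covered == {"h0", "h1"}

    def test_upregulated_restriction_drops_axes(self):
        g, axes, hubs = make_cover_instance([{0, 1}, {0, 1}], 2)
        cover = minimal_axis_cover(axes, hubs, g, upregulated=["r1"])
        assert [a.receptor for a in cover.axes] == ["r1"]

    def test_greedy_flagged_not_minimal(self):
        g, axes, hubs = make_cover_instance([{0, 1}, {1, 2}, {0, 2}], 3)
        cover = minimal_axis_cover(axes, hubs, g, exact_limit=2)
        assert cover.feasible and not cover.minimal
        # greedy can never beat the exact optimum
        exact = minimal_axis_cover(axes, hubs, g)
        assert exact.minimal
        assert exact.size <= cover.size

    def test_planted_triad_recovered(self, small_bundle):
        from cardionet import grow_network

        _, _, db, truth = small_bundle
        net = grow_network(truth.conserved, db)
        hubs = identify_hubs(net, n_hubs=9)
        cover = minimal_axis_cover(db.axes, hubs, net, upregulated=truth.conserved_up)
        assert cover.minimal and cover.feasible
        assert tuple(sorted(a.name for a in cover.axes)) == tuple(truth.planted_cover)
        # minimality certificate against brute-force enumeration
        from cardionet.hubrank import axis_hits

        _, hits = axis_hits(db.axes, hubs, net, truth.conserved_up)
        assert min_cover_size(list(hits.values()), set(hubs.hubs)) == cover.size

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_exact_equals_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_hubs = int(rng.integers(1, 9))
        n_axes = int(rng.integers(1, 10))
        hit_map = [
            set(int(h) for h in rng.choice(n_hubs, size=rng.integers(0, n_hubs + 1), replace=False))
            for _ in range(n_axes)
        ]
        g, axes, hubs = make_cover_instance(hit_map, n_hubs)
        cover = minimal_axis_cover(axes, hubs, g)
        expected = min_cover_size([frozenset(f"h{i}" for i in s) for s in hit_map], set(hubs.hubs))
        if expected is None:
            assert not cover.feasible
        else:
            assert cover.feasible and cover.minimal
            assert cover.size == expected
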