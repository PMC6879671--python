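"""Centrality, hub/bottleneck calls, subnetwork induction."""

import networkx as nx
import numpy as np
import pytest

from coexdriver.io import GenePanel
from coexdriver.topology import (
    betweenness_centrality,
    build_rapin,
    degree_centrality,
    edge_node_ratio,
    hub_threshold,
    select_bottlenecks,
    select_hubs,
)
from conftest import random_simple_graph
from oracles import brute_betweenness


class TestDegree:
    def test_triangle(self):
        assert set(degree_centrality(nx.cycle_graph(3)).values()) == {2}

    def test_star(self):
        dc = degree_centrality(nx.star_graph(4))
        assert dc[0] == 4 and all(dc[i] == 1 for i in range(1, 5))

    def test_isolated_node(self):
        graph = nx.Graph()
        graph.add_node("X")
        assert degree_centrality(graph) == {"X": 0}


class TestBetweenness:
    def test_path_graph_center(self):
        bc = betweenness_centrality(nx.path_graph(3))
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_star_center_is_one(self):
        # raw count: all 6 leaf pairs route through the center
        bc = betweenness_centrality(nx.star_graph(4))
        assert bc[0] == pytest.approx(1.0)

    def test_complete_graph_all_zero(self):
        assert set(betweenness_centrality(nx.complete_graph(4)).values()) == {0.0}

    def test_below_three_nodes_all_zero(self):
        assert betweenness_centrality(nx.path_graph(2)) == {0: 0.0, 1: 0.0}

    def test_matches_path_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            graph = random_simple_graph(rng, max_nodes=15)
            got = betweenness_centrality(graph)
            want = brute_betweenness(graph)
            for node in graph.nodes():
                assert got[node] == pytest.approx(want[node], abs=1e-9)

    def test_disconnected_pairs_contribute_nothing(self):
        graph = nx.path_graph(3)
        graph.add_edge("x", "y")  # separate component
        bc = betweenness_centrality(graph)
        assert bc[1] > 0 and bc["x"] == bc["y"] == 0.0


class TestHubs:
    def test_star_threshold_hand_arithmetic(self):
        # star on 11 nodes: degrees {10} + 10x{1}; mean 1.818, sample SD 2.713
        graph = nx.star_graph(10)
        degrees = list(degree_centrality(graph).values())
        assert hub_threshold(degrees) == pytest.approx(7.2455, abs=1e-3)
        assert select_hubs(graph) == {0}

    def test_regular_graph_has_no_hubs(self):
        assert select_hubs(nx.cycle_graph(6)) == set()

    def test_two_node_graph_has_no_hubs(self):
        assert select_hubs(nx.path_graph(2)) == set()

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            select_hubs(nx.Graph())

    def test_population_sd_variant(self):
        degrees = [10] + [1] * 10
        assert hub_threshold(degrees, sd_mode="population") < hub_threshold(degrees)


class TestBottlenecks:
    def test_top_quarter_of_eight_distinct(self):
        graph = nx.Graph()
        bc = {f"n{i}": i / 10 for i in range(8)}
        graph.add_nodes_from(bc)
        picked = select_bottlenecks(graph, fraction=0.25, bc=bc)
        assert picked == {"n7", "n6"}

    def test_ties_straddling_cut_are_included(self):
        graph = nx.Graph()
        bc = {"a": 0.9, "b": 0.5, "c": 0.5, "d": 0.5, "e": 0.1, "f": 0.0, "g": 0.0, "h": 0.0}
        graph.add_nodes_from(bc)
        assert select_bottlenecks(graph, fraction=0.25, bc=bc) == {"a", "b", "c", "d"}

    def test_path_graph_middle_is_bottleneck(self):
        assert 2 in select_bottlenecks(nx.path_graph(5), fraction=0.25)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            select_bottlenecks(nx.path_graph(3), fraction=1.5)


class TestRapin:
    def test_induction_rule(self):
        graph = nx.Graph([("A", "C"), ("A", "D")])
        graph.add_node("B")
        panel = GenePanel(name="p", members={"C"}, category_of={"C": "seed"})
        result = build_rapin(graph, hubs={"A"}, bottlenecks={"B"}, panel=panel)
        assert set(result.subnetwork.nodes()) == {"A", "B", "C"}
        assert set(map(frozenset, result.subnetwork.edges())) == {frozenset(("A", "C"))}

    def test_disjoint_sets_yield_edgeless_subnetwork(self):
        graph = nx.Graph([("A", "X"), ("B", "Y"), ("C", "Z")])
        panel = GenePanel(name="p", members={"C"}, category_of={"C": "seed"})
        result = build_rapin(graph, hubs={"A"}, bottlenecks={"B"}, panel=panel)
        assert result.subnetwork.number_of_edges() == 0

    def test_overlapping_categories_counted_once(self):
        graph = nx.Graph([("A", "B")])
        panel = GenePanel(name="p", members={"A"}, category_of={"A": "seed"})
        result = build_rapin(graph, hubs={"A"}, bottlenecks={"A"}, panel=panel)
        assert result.subnetwork.number_of_nodes() == 1

    def test_missing_panel_genes_reported(self):
        graph = nx.Graph([("A", "B")])
        panel = GenePanel(
            name="p", members={"A", "GHOST"},
            category_of={"A": "seed", "GHOST": "seed"},
        )
        result = build_rapin(graph, hubs=set(), bottlenecks=set(), panel=panel)
        assert result.missing_panel_genes == {"GHOST"}

    def test_subnetwork_edges_all_exist_in_input(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            graph = random_simple_graph(rng, max_nodes=20)
            nodes = list(graph.nodes())
            hubs = set(nodes[: len(nodes) // 3])
            panel_gene = nodes[-1]
            panel = GenePanel(
                name="p", members={panel_gene}, category_of={panel_gene: "seed"}
            )
            result = build_rapin(graph, hubs, set(nodes[-3:-1]), panel)
            for edge in result.subnetwork.edges():
                assert graph.has_edge(*edge)

    def test_empty_union_rejected(self):
        graph = nx.Graph([("A", "B")])
        panel = GenePanel(name="p", members={"Z"}, category_of={"Z": "seed"})
        with pytest.raises(ValueError):
            build_rapin(graph, set(), set(), panel)


def test_edge_node_ratio():
    assert edge_node_ratio(nx.complete_graph(4)) == pytest.approx(1.5)
    with pytest.raises(ValueError):
        edge_node_ratio(nx.Graph())
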