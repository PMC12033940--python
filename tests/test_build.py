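"""Case-network construction: filtering, neighbourhood addition, enrichment."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ppinet.build import (
    add_condition_neighbourhood,
    build_case_network,
    enrich_connect,
    filter_by_universe,
)
from conftest import bfs_distances, random_graph


def graph_from_edges(edges, name="g"):
    g = nx.Graph(name=name)
    for u, v in edges:
        g.add_edge(u, v, confidence=1.0)
    return g


class TestFilterByUniverse:
    def test_path_graph_induced_subgraph(self):
        ref = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        out = filter_by_universe(ref, {"A", "B", "D"})
        assert set(out.nodes) == {"A", "B", "D"}
        assert set(map(frozenset, out.edges)) == {frozenset({"A", "B"})}

    def test_superset_universe_is_identity(self):
        ref = graph_from_edges([("A", "B"), ("B", "C")])
        out = filter_by_universe(ref, {"A", "B", "C", "Z"})
        assert set(out.nodes) == set(ref.nodes)
        assert set(out.edges) == set(ref.edges)

    def test_empty_intersection_raises_with_diagnostic(self):
        ref = graph_from_edges([("A", "B")])
        with pytest.raises(ValueError, match="X1"):
            filter_by_universe(ref, {"X1", "X2"})

    def test_matches_brute_force_membership_check(self, rng):
        ref = random_graph(rng, n_max=200, p=0.03)
        universe = set(rng.choice(sorted(ref.nodes), size=min(50, len(ref)), replace=False))
        out = filter_by_universe(ref, universe)
        expected_edges = {
            frozenset((u, v))
            for u, v in ref.edges
            if u in universe and v in universe
        }
        assert set(out.nodes) == set(ref.nodes) & universe
        assert set(map(frozenset, out.edges)) == expected_edges
        for u, v in out.edges:
            assert out.edges[u, v]["confidence"] == ref.edges[u, v]["confidence"]


class TestAddConditionNeighbourhood:
    def test_star_centre_pulls_in_leaves(self):
        ref = graph_from_edges([("S", "A"), ("S", "B"), ("S", "C")])
        net = ref.subgraph({"A"}).copy()
        out = add_condition_neighbourhood(net, ref, {"S"})
        assert set(out.nodes) == {"A", "B", "C", "S"}
        assert out.number_of_edges() == 3

    def test_no_new_neighbours_is_identity(self):
        ref = graph_from_edges([("A", "B"), ("B", "C")])
        net = ref.copy()
        out = add_condition_neighbourhood(net, ref, {"B"})
        assert set(out.nodes) == set(net.nodes)
        assert set(out.edges) == set(net.edges)

    def test_neighbour_count_on_fixture(self):
        # condition protein with 7 reference neighbours, 3 already present
        ref = graph_from_edges([("COND", f"N{i}") for i in range(7)])
        net = ref.subgraph({"N0", "N1", "N2"}).copy()
        out = add_condition_neighbourhood(net, ref, {"COND"})
        added = set(out.nodes) - set(net.nodes) - {"COND"}
        assert len(added) == 4

    def test_absent_condition_protein_warned_and_skipped(self):
        ref = graph_from_edges([("A", "B")])
        net = ref.copy()
        with pytest.warns(UserWarning, match="GHOST"):
            out = add_condition_neighbourhood(net, ref, {"GHOST"})
        assert set(out.nodes) == {"A", "B"}


class TestEnrichConnect:
    def test_single_bridge_on_path(self):
        ref = graph_from_edges([("A", "B"), ("B", "C")])
        net = ref.subgraph({"A", "C"}).copy()
        out, report = enrich_connect(net, ref)
        assert set(out.nodes) == {"A", "B", "C"}
        assert report.connected
        assert report.n_bridge_nodes_added == 1

    def test_already_connected_is_identity(self):
        ref = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        out, report = enrich_connect(ref.copy(), ref)
        assert set(out.nodes) == set(ref.nodes)
        assert report.n_bridge_nodes_added == 0
        assert report.connected

    def test_tied_paths_choose_lexicographically_smaller_interior(self):
        # two 2-hop paths A-B-D and A-C-D: B must win
        ref = graph_from_edges([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        net = ref.subgraph({"A", "D"}).copy()
        out, report = enrich_connect(net, ref)
        assert set(out.nodes) == {"A", "B", "D"}
        # oracle: enumerate all shortest paths, apply the stated tie-break
        tied = sorted(
            tuple(p[1:-1]) for p in nx.all_shortest_paths(ref, "A", "D")
        )
        assert report.merges[0]["added"] == list(tied[0])

    def test_unconnectable_reference_flags_partial_result(self):
        ref = graph_from_edges([("A", "B"), ("C", "D")])
        net = ref.subgraph({"A", "C"}).copy()
        with pytest.warns(UserWarning, match="does not connect"):
            out, report = enrich_connect(net, ref)
        assert not report.connected

    @pytest.mark.parametrize("seed", range(10))
    def test_bridges_lie_on_reference_shortest_paths(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_graph(rng, n_max=40, p=0.12)
        if not nx.is_connected(ref):
            ref = ref.subgraph(max(nx.connected_components(ref), key=len)).copy()
        keep = set(
            rng.choice(sorted(ref.nodes), size=max(2, len(ref) // 4), replace=False)
        )
        net = ref.subgraph(keep).copy()
        out, report = enrich_connect(net, ref)
        assert report.connected
        assert nx.is_connected(out)
        # monotone growth and induced closure
        assert keep <= set(out.nodes)
        expected = {
            frozenset((u, v))
            for u, v in ref.edges
            if u in out.nodes and v in out.nodes
        }
        assert set(map(frozenset, out.edges)) == expected
        # every added node sits on a shortest reference path between nodes
        # that were present before its merge step
        for merge in report.merges:
            a, b = merge["endpoints"]
            before = set(merge["nodes_before"])
            assert a in before and b in before
            da = bfs_distances(ref, a)
            assert da[b] == merge["distance"]
            for node in merge["added"]:
                db = bfs_distances(ref, node)
                assert da[node] + db[b] == da[b]

    def test_termination_bound(self, rng):
        ref = random_graph(rng, n_max=40, p=0.2)
        if not nx.is_connected(ref):
            ref = ref.subgraph(max(nx.connected_components(ref), key=len)).copy()
        keep = set(list(sorted(ref.nodes))[:: max(1, len(ref) // 6)])
        net = ref.subgraph(keep).copy()
        n_components = nx.number_connected_components(net)
        _, report = enrich_connect(net, ref)
        assert len(report.merges) <= n_components - 1 or n_components == 1


class TestBuildCaseNetwork:
    def test_identity_when_universe_covers_connected_reference(self, rng):
        ref = random_graph(rng, n_max=25, p=0.4)
        if not nx.is_connected(ref):
            ref = ref.subgraph(max(nx.connected_components(ref), key=len)).copy()
        out, report = build_case_network(ref, set(ref.nodes), set())
        assert set(out.nodes) == set(ref.nodes)
        assert report.n_condition_added == 0
        assert report.n_bridge_nodes_added == 0
        assert report.connected

    def test_condition_hub_added_from_other_community(self):
        # two cliques joined by one edge; universe is clique 1, condition
        # protein is a hub of clique 2
        c1 = [f"A{i}" for i in range(4)]
        c2 = [f"B{i}" for i in range(4)]
        edges = list(itertools.combinations(c1, 2)) + list(itertools.combinations(c2, 2))
        edges.append(("A0", "B0"))
        ref = graph_from_edges(edges)
        out, report = build_case_network(ref, set(c1), {"B0"})
        assert report.n_condition_added == 1
        assert report.connected
        assert "B0" in out.nodes

    def test_disconnected_filtered_graph_gets_bridged(self):
        ref = graph_from_edges(
            [("A", "X"), ("X", "B"), ("B", "Y"), ("Y", "C"), ("A", "C")]
        )
        out, report = build_case_network(ref, {"A", "B", "C"}, set())
        assert nx.is_connected(out)
        assert report.connected
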