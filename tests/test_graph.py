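import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import topocomm as tc
from topocomm.graph import GraphParseError

from conftest import clique_edges, random_graph


edge_lists = st.lists(
    st.tuples(st.integers(0, 15), st.integers(0, 15)), min_size=1, max_size=60
)


class TestBuildGraph:
    def test_symmetrize_and_drop_self_loops(self):
        g = tc.build_graph([("a", "b"), ("b", "a"), ("c", "c")], directed=True)
        assert g.m == 1
        assert g.adj["a"] == {"b"}
        assert g.adj["c"] == frozenset()

    def test_self_regulation_arcs_contribute_no_edges(self):
        # a regulatory-network-style input with 5 self-regulation arcs
        regulatory = [("crp", "araC"), ("araC", "araBAD"), ("crp", "araBAD"),
                      ("fnr", "narL"), ("narL", "narGHJI")]
        self_loops = [(x, x) for x in ["crp", "araC", "fnr", "narL", "lexA"]]
        g = tc.build_graph(regulatory + self_loops, directed=True)
        assert g.m == len(regulatory)
        assert all(v not in g.adj[v] for v in g.nodes)

    def test_edge_order_invariance(self):
        edges = clique_edges(["a", "b", "c", "d"]) + [("d", "e"), ("e", "f")]
        g1 = tc.build_graph(edges)
        g2 = tc.build_graph(list(reversed([(v, u) for u, v in edges])))
        assert g1 == g2
        assert g1.edges() == g2.edges()

    def test_mixed_token_types_canonicalized(self):
        g1 = tc.build_graph([(1, 2), (2, 3)])
        g2 = tc.build_graph([("1", "2"), ("2", "3")])
        assert g1 == g2

    def test_malformed_record_raises(self):
        with pytest.raises(GraphParseError, match="a"):
            tc.build_graph([("a",)])

    def test_explicit_isolated_nodes(self):
        g = tc.build_graph([], nodes=["x", "y"])
        assert g.m == 0 and g.isolated_nodes() == {"x", "y"}

    @given(edges=edge_lists)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariants(self, edges):
        g = tc.build_graph(edges)
        # symmetry, loop-freeness, degree sum
        for u in g.nodes:
            assert u not in g.adj[u]
            for v in g.adj[u]:
                assert u in g.adj[v]
        assert sum(g.degree(v) for v in g.nodes) == 2 * g.m
        # idempotence / edge-order invariance
        rng = np.random.default_rng(0)
        perm = list(edges)
        rng.shuffle(perm)
        assert tc.build_graph(perm) == g


class TestComponents:
    def test_two_triangles_and_lone_node(self):
        g = tc.build_graph(
            clique_edges(["a", "b", "c"]) + clique_edges(["x", "y", "z"]),
            nodes=["lone"])
        d = tc.connected_components(g)
        assert [len(c) for c in d.components] == [3, 3]
        assert d.isolated == {"lone"}

    def test_connected_graph_single_component(self):
        g = tc.build_graph([("a", "b"), ("b", "c")])
        d = tc.connected_components(g)
        assert len(d.components) == 1 and not d.isolated

    def test_many_components_against_networkx(self):
        # 29 disjoint random subgraphs plus 5 degree-0 nodes
        rng = np.random.default_rng(42)
        edges, nodes = [], []
        for c in range(29):
            size = int(rng.integers(3, 9))
            ids = [f"c{c:02d}_{i}" for i in range(size)]
            nodes += ids
            for i in range(1, size):  # random spanning tree keeps it connected
                j = int(rng.integers(0, i))
                edges.append((ids[i], ids[j]))
            for i in range(size):
                for j in range(i + 1, size):
                    if rng.random() < 0.3:
                        edges.append((ids[i], ids[j]))
        nodes += [f"iso{i}" for i in range(5)]
        g = tc.build_graph(edges, nodes=nodes)
        d = tc.connected_components(g)
        assert len(d.components) == 29
        assert len(d.isolated) == 5
        nxg = nx.Graph(edges)
        nx_comps = {frozenset(c) for c in nx.connected_components(nxg)}
        assert {frozenset(c) for c in d.components} == nx_comps

    def test_deterministic_ordering(self):
        g = tc.build_graph(clique_edges(["b", "c", "d"]) + [("a", "e")])
        d = tc.connected_components(g)
        assert [min(c) for c in d.components] == ["b", "a"]  # size desc


class TestDistances:
    def test_path_and_self(self):
        g = tc.build_graph([("a", "b"), ("b", "c")])
        assert tc.shortest_path_length(g, "a", "c") == 2
        assert tc.shortest_path_length(g, "b", "b") == 0

    def test_disconnected_pair_infinite(self):
        g = tc.build_graph([("a", "b"), ("c", "d")])
        assert tc.shortest_path_length(g, "a", "d") == math.inf

    def test_unknown_node_raises(self):
        g = tc.build_graph([("a", "b")])
        with pytest.raises(KeyError):
            tc.shortest_path_length(g, "a", "zz")

    def test_matches_networkx_and_triangle_inequality(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, n=25, p=0.15)
        nxg = nx.Graph(g.edges())
        nxg.add_nodes_from(g.nodes)
        nodes = list(g.nodes)
        for _ in range(60):
            u, v, w = (nodes[i] for i in rng.integers(0, len(nodes), 3))
            duv = tc.shortest_path_length(g, u, v)
            expected = nx.shortest_path_length(nxg, u, v) \
                if nx.has_path(nxg, u, v) else math.inf
            assert duv == expected
            dvw = tc.shortest_path_length(g, v, w)
            duw = tc.shortest_path_length(g, u, w)
            assert duw <= duv + dvw


class TestEdgeCounts:
    def test_k4_with_pendant(self, k4_pendant):
        assert tc.edge_counts(k4_pendant, {"a", "b", "c", "d"}) == (6, 1)

    def test_whole_graph_and_empty_set(self, k4_pendant):
        assert tc.edge_counts(k4_pendant, set(k4_pendant.nodes)) == (7, 0)
        assert tc.edge_counts(k4_pendant, set()) == (0, 0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng, n=30, p=0.2)
        for _ in range(20):
            S = {v for v in g.nodes if rng.random() < 0.4}
            internal = sum(1 for u, v in g.edges() if u in S and v in S)
            external = sum(1 for u, v in g.edges() if (u in S) != (v in S))
            assert tc.edge_counts(g, S) == (internal, external)

    def test_partition_conservation(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, n=20, p=0.3)
        S = set(list(g.nodes)[:8])
        rest = set(g.nodes) - S
        i_s, e_s = tc.edge_counts(g, S)
        i_r, _ = tc.edge_counts(g, rest)
        assert i_s + e_s + i_r == g.m


class TestEdgesBetween:
    def test_two_triangles_two_bridges(self):
        g = tc.build_graph(
            clique_edges(["a", "b", "c"]) + clique_edges(["x", "y", "z"])
            + [("a", "x"), ("b", "y")])
        assert tc.edges_between(g, {"a", "b", "c"}, {"x", "y", "z"}) == 2

    def test_disjoint_components_zero(self):
        g = tc.build_graph([("a", "b"), ("x", "y")])
        assert tc.edges_between(g, {"a", "b"}, {"x", "y"}) == 0

    def test_overlapping_sets_raise(self):
        g = tc.build_graph([("a", "b")])
        with pytest.raises(ValueError):
            tc.edges_between(g, {"a"}, {"a", "b"})

    def test_sums_to_external_over_spanning_cover(self):
        rng = np.random.default_rng(11)
        g = random_graph(rng, n=24, p=0.25)
        nodes = list(g.nodes)
        parts = [set(nodes[:8]), set(nodes[8:16]), set(nodes[16:])]
        for S in parts:
            total = sum(tc.edges_between(g, S, T) for T in parts if T is not S)
            assert total == tc.edge_counts(g, S)[1]
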