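"""Graph model: mutation, capacity, filtering, search, collapse, stats."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pymedusa as pm
from pymedusa.errors import (
    DuplicateEdgeError,
    DuplicateNodeError,
    EdgeTypeCapacityError,
    InvalidPatternError,
    UnknownNodeError,
)
from pymedusa.fixtures import FixtureSpec, generate

from conftest import mknet


class TestMutation:
    def test_add_then_remove_node_is_identity(self):
        net = pm.Network()
        net.add_node(pm.Node(name="A"))
        net.remove_node("A")
        assert net == pm.Network()

    def test_duplicate_node_rejected(self):
        net = mknet("A")
        with pytest.raises(DuplicateNodeError):
            net.add_node(pm.Node(name="A"))

    def test_edge_needs_existing_endpoints(self):
        net = mknet("A")
        with pytest.raises(UnknownNodeError):
            net.add_edge(pm.Edge(source="A", target="Z"))

    def test_eight_types_fit_ninth_rejected(self):
        net = mknet("AB")
        for t in range(1, 9):
            net.add_edge(pm.Edge(source="A", target="B", edge_type=t))
        assert net.n_edges == 8
        with pytest.raises(DuplicateEdgeError):
            net.add_edge(pm.Edge(source="A", target="B", edge_type=8))
        with pytest.raises(ValueError):
            pm.Edge(source="A", target="B", edge_type=9)

    def test_directed_capacity_counts_both_directions(self):
        net = pm.Network(directed=True)
        net.add_node(pm.Node(name="A"))
        net.add_node(pm.Node(name="B"))
        for t in range(1, 5):
            net.add_edge(pm.Edge(source="A", target="B", edge_type=t))
            net.add_edge(pm.Edge(source="B", target="A", edge_type=t))
        with pytest.raises(EdgeTypeCapacityError):
            net.add_edge(pm.Edge(source="A", target="B", edge_type=5))

    def test_remove_node_drops_incident_edges(self):
        net = mknet("ABC", [("A", "B"), ("B", "C")])
        net.remove_node("B")
        assert net.node_names == ["A", "C"]
        assert net.n_edges == 0

    def test_self_loops_rejected(self):
        with pytest.raises(ValueError):
            pm.Edge(source="A", target="A")

    def test_undirected_identity_is_order_normalised(self):
        net = mknet("AB", [("A", "B")])
        with pytest.raises(DuplicateEdgeError):
            net.add_edge(pm.Edge(source="B", target="A"))


class TestFilterEdges:
    def test_threshold_keeps_heavy_edges(self):
        net = mknet("ABCD", [("A", "B", 1, 0.2), ("B", "C", 1, 0.5), ("C", "D", 1, 0.9)])
        out = pm.filter_edges(net, 0.5)
        assert out.n_edges == 2
        assert out.node_names == ["A", "B", "C", "D"]  # nodes never dropped

    def test_zero_threshold_is_identity_on_edges(self):
        net = mknet("ABC", [("A", "B", 1, 0.1), ("B", "C", 2, 0.0)])
        assert pm.filter_edges(net, 0.0).edges == net.edges

    def test_type_filter_matches_brute_force(self):
        fx = generate(FixtureSpec(kind="multi_edge", n=20, params={"p": 0.3}, seed=7))
        out = pm.filter_edges(fx.network, 0.3, types={1, 3})
        expected = [
            e for e in fx.network.edges if e.weight >= 0.3 and e.edge_type in (1, 3)
        ]
        assert out.edges == expected

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pm.filter_edges(mknet("A"), 1.5)

    @settings(derandomize=True, max_examples=40)
    @given(a=st.floats(0, 1), b=st.floats(0, 1), seed=st.integers(0, 20))
    def test_monotone_in_threshold(self, a, b, seed):
        a, b = min(a, b), max(a, b)
        fx = generate(FixtureSpec(kind="multi_edge", n=12, params={"p": 0.3}, seed=seed))
        at_b = {(e.source, e.target, e.edge_type) for e in pm.filter_edges(fx.network, b).edges}
        at_a = {(e.source, e.target, e.edge_type) for e in pm.filter_edges(fx.network, a).edges}
        assert at_b <= at_a


class TestIsolate:
    def test_full_focus_returns_all_edges(self, triangle):
        assert pm.isolate(triangle, {"A", "B", "C"}) == triangle.edges

    def test_empty_focus_returns_nothing(self, triangle):
        assert pm.isolate(triangle, set()) == []

    def test_star_center_touches_everything(self):
        net = mknet("cXYZ", [("c", "X"), ("c", "Y"), ("c", "Z")])
        assert pm.isolate(net, {"c"}) == net.edges

    def test_unknown_focus_node_rejected(self, triangle):
        with pytest.raises(UnknownNodeError):
            pm.isolate(triangle, {"nope"})

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10), split=st.integers(1, 10))
    def test_union_distributes(self, seed, split):
        fx = generate(FixtureSpec(kind="random_graph", n=12, params={"p": 0.3}, seed=seed))
        names = fx.network.node_names
        s1, s2 = set(names[:split]), set(names[split:])
        key = lambda edges: {(e.source, e.target, e.edge_type) for e in edges}
        assert key(pm.isolate(fx.network, s1 | s2)) == key(
            pm.isolate(fx.network, s1)
        ) | key(pm.isolate(fx.network, s2))


class TestSearch:
    def test_wildcard_matches_all_names(self, triangle):
        assert pm.search(triangle, ".*", fields={"name"}) == {"A", "B", "C"}

    def test_anchored_prefix(self):
        net = mknet(["TP53", "TP63", "BRCA1"])
        assert pm.search(net, "^TP", fields={"name"}) == {"TP53", "TP63"}

    def test_annotation_matches_linear_scan(self):
        net = pm.Network()
        import numpy as np

        rng = np.random.default_rng(5)
        words = ["kinase", "phosphatase", "receptor", "ligase"]
        for i in range(50):
            ann = f"{words[rng.integers(4)]} domain protein" if rng.uniform() < 0.7 else None
            net.add_node(pm.Node(name=f"p{i:02d}", annotation=ann))
        import re

        expected = {
            n.name
            for n in net.nodes
            if n.annotation is not None and re.search("kinase", n.annotation)
        }
        assert pm.search(net, "kinase", fields={"annotation"}) == expected

    def test_unset_annotation_never_matches(self):
        net = mknet("AB")
        assert pm.search(net, ".*", fields={"annotation"}) == set()

    def test_invalid_regex_raises_parse_error(self, triangle):
        with pytest.raises(InvalidPatternError):
            pm.search(triangle, "([")


class TestCollapseExpand:
    def test_roundtrip_restores_network_exactly(self):
        fx = generate(FixtureSpec(kind="multi_edge", n=10, params={"p": 0.4}, seed=3))
        names = fx.network.node_names
        collapsed = pm.collapse(fx.network, set(names[:4]), "META")
        assert pm.expand(collapsed, "META") == fx.network

    def test_triangle_aggregation_takes_max_weight(self):
        net = mknet("ABC", [("A", "B", 2, 0.3), ("A", "C", 2, 0.8), ("B", "C", 1, 0.5)])
        out = pm.collapse(net, {"B", "C"}, "M")
        assert out.node_names == ["A", "M"]
        (edge,) = out.edges
        assert (edge.edge_type, edge.weight) == (2, 0.8)

    def test_isolated_group_collapses_to_degree_zero(self):
        net = mknet("ABCD", [("A", "B")])
        out = pm.collapse(net, {"C", "D"}, "M")
        assert pm.stats(out).degree["M"] == 0

    def test_group_must_have_two_members(self, triangle):
        with pytest.raises(pm.MedusaError):
            pm.collapse(triangle, {"A"}, "M")

    def test_expand_unknown_meta_rejected(self, triangle):
        with pytest.raises(pm.MedusaError):
            pm.expand(triangle, "M")

    def test_meta_name_collision_rejected(self, triangle):
        with pytest.raises(DuplicateNodeError):
            pm.collapse(triangle, {"A", "B"}, "C")


class TestStats:
    def test_triangle(self, triangle):
        s = pm.stats(triangle)
        assert set(s.degree.values()) == {2}
        assert (s.n_components, s.density, s.n_pairs) == (1, 1.0, 3)

    def test_empty_network_yields_zeros(self):
        s = pm.stats(pm.Network())
        assert (s.n_nodes, s.n_edges, s.n_components, s.density) == (0, 0, 0, 0.0)

    def test_components_match_networkx(self):
        import networkx as nx

        fx = generate(FixtureSpec(kind="random_graph", n=40, params={"p": 0.1}, seed=11))
        g = nx.Graph()
        g.add_nodes_from(fx.network.node_names)
        g.add_edges_from((e.source, e.target) for e in fx.network.edges)
        assert pm.stats(fx.network).n_components == nx.number_connected_components(g)

    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sum_law(self, seed):
        fx = generate(FixtureSpec(kind="multi_edge", n=15, params={"p": 0.3}, seed=seed))
        s = pm.stats(fx.network)
        assert sum(s.degree.values()) == 2 * s.n_edges
        assert 0.0 <= s.density <= 1.0
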