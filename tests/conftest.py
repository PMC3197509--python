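"""Shared test helpers: compact network builders and random documents."""

from __future__ import annotations

import pytest

from pymedusa import Edge, Network, Node
from pymedusa.fixtures import random_document, random_network  # noqa: F401 (re-export)


def mknet(nodes, edges=(), directed=False):
    """Build a network from node names and (src, tgt[, type[, weight]]) tuples."""
    net = Network(directed=directed)
    for name in nodes:
        net.add_node(Node(name=name))
    for spec in edges:
        src, tgt, *rest = spec
        etype = rest[0] if rest else 1
        weight = rest[1] if len(rest) > 1 else 1.0
        net.add_edge(Edge(source=src, target=tgt, edge_type=etype, weight=weight))
    return net


@pytest.fixture
def triangle():
    return mknet("ABC", [("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def two_triangles():
    return mknet(
        ["a1", "a2", "a3", "b1", "b2", "b3"],
        [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
         ("b1", "b2"), ("b2", "b3"), ("b1", "b3")],
    )
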