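"""Multi-edged weighted graph model.

The container is a multigraph in which a pair of nodes may be linked by up
to eight parallel edges, each tagged with an integer ``edge_type`` in 1..8
(one type per evidence channel: co-expression, text mining, homology, ...)
and an optional confidence weight in [0, 1].  Networks are directed or
undirected as a whole; individual edges may override the flag.

Node coordinates are normalised to the unit square using screen convention:
origin at the top-left corner, y grows downward.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .errors import (
    DuplicateEdgeError,
    DuplicateNodeError,
    EdgeTypeCapacityError,
    InvalidPatternError,
    MedusaError,
    UnknownNodeError,
)

SHAPES = ("circle", "rectangle", "triangle", "diamond", "hexagon")
ORIENTATIONS = ("auto", "up", "down", "straight")
MAX_EDGE_TYPES = 8

DEFAULT_NODE_COLOR = (180, 180, 180)


def _check_color(color) -> tuple[int, int, int]:
    r, g, b = color
    for c in (r, g, b):
        if not (isinstance(c, int) and 0 <= c <= 255):
            raise ValueError(f"color components must be integers in 0..255, got {color!r}")
    return (r, g, b)


@dataclass(frozen=True)
class Node:
    """A named vertex with style attributes.

    ``extras`` preserves unknown ``key:value`` attribute tokens read from a
    medusa file so they survive a read/write round trip untouched.
    """

    name: str
    color: tuple[int, int, int] = DEFAULT_NODE_COLOR
    shape: str = "circle"
    x: Optional[float] = None
    y: Optional[float] = None
    annotation: Optional[str] = None
    url: Optional[str] = None
    extras: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.name or any(ch.isspace() for ch in self.name):
            raise ValueError(f"node name must be non-empty and contain no whitespace: {self.name!r}")
        object.__setattr__(self, "color", _check_color(self.color))
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        for label, v in (("x", self.x), ("y", self.y)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{label} coordinate must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class Edge:
    """A typed, optionally weighted and directed connection.

    ``directed`` of ``None`` inherits the owning network's flag.
    ``orientation`` controls which way a multi-edge Bezier bows when drawn.
    """

    source: str
    target: str
    edge_type: int = 1
    weight: float = 1.0
    directed: Optional[bool] = None
    orientation: str = "auto"
    extras: tuple[str, ...] = ()

    def __post_init__(self):
        if not (isinstance(self.edge_type, int) and 1 <= self.edge_type <= MAX_EDGE_TYPES):
            raise ValueError(f"edge_type must be an integer in 1..{MAX_EDGE_TYPES}, got {self.edge_type!r}")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"weight must lie in [0, 1], got {self.weight!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}; expected one of {ORIENTATIONS}")
        if self.source == self.target:
            raise ValueError(f"self-loops are not supported (node {self.source!r})")

    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair, lexicographically normalised."""
        return tuple(sorted((self.source, self.target)))


@dataclass
class CollapseRecord:
    """Everything needed to undo a :func:`collapse`: the removed member
    nodes and every edge that touched the group."""

    meta_name: str
    members: tuple[Node, ...]
    edges: tuple[Edge, ...]


class Network:
    """Multigraph container with a directedness flag.

    Nodes are stored by unique name; edge identity is
    ``(source, target, edge_type)``, with endpoints order-normalised first
    for undirected networks so that A–B and B–A denote the same record.
    """

    def __init__(self, directed: bool = False, background_image: Optional[str] = None):
        self.directed = directed
        self.background_image = background_image
        self._nodes: dict[str, Node] = {}
        self._edges: dict[tuple[str, str, int], Edge] = {}
        self._collapsed: dict[str, CollapseRecord] = {}

    # -- basic access ------------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return sorted(self._nodes)

    @property
    def nodes(self) -> list[Node]:
        return [self._nodes[n] for n in sorted(self._nodes)]

    @property
    def edges(self) -> list[Edge]:
        return [self._edges[k] for k in sorted(self._edges)]

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node(self, name: str) -> Node:
        try:
            return self._nodes[name]
        except KeyError:
            raise UnknownNodeError(f"unknown node {name!r}") from None

    def has_node(self, name: str) -> bool:
        return name in self._nodes

    def _edge_key(self, edge: Edge) -> tuple[str, str, int]:
        if self.directed:
            return (edge.source, edge.target, edge.edge_type)
        a, b = edge.pair()
        return (a, b, edge.edge_type)

    def edges_between(self, a: str, b: str) -> list[Edge]:
        pair = tuple(sorted((a, b)))
        return [e for e in self.edges if e.pair() == pair]

    # -- mutation ----------------------------------------------------------

    def add_node(self, node: Node) -> "Network":
        if node.name in self._nodes:
            raise DuplicateNodeError(f"node {node.name!r} already exists")
        self._nodes[node.name] = node
        return self

    def update_node(self, node: Node) -> "Network":
        """Replace an existing node's attributes, keeping its edges."""
        if node.name not in self._nodes:
            raise UnknownNodeError(f"unknown node {node.name!r}")
        self._nodes[node.name] = node
        return self

    def add_edge(self, edge: Edge) -> "Network":
        for end in (edge.source, edge.target):
            if end not in self._nodes:
                raise UnknownNodeError(f"edge endpoint {end!r} is not a node in the network")
        if not self.directed and edge.source > edge.target:
            edge = replace(edge, source=edge.target, target=edge.source)
        key = self._edge_key(edge)
        if key in self._edges:
            raise DuplicateEdgeError(
                f"edge ({edge.source!r}, {edge.target!r}) with type {edge.edge_type} already exists"
            )
        n_parallel = len(self.edges_between(edge.source, edge.target))
        if n_parallel >= MAX_EDGE_TYPES:
            raise EdgeTypeCapacityError(
                f"edge-type capacity: pair ({edge.source!r}, {edge.target!r}) already carries "
                f"{MAX_EDGE_TYPES} edge records"
            )
        self._edges[key] = edge
        return self

    def remove_node(self, name: str) -> "Network":
        if name not in self._nodes:
            raise UnknownNodeError(f"unknown node {name!r}")
        del self._nodes[name]
        self._edges = {k: e for k, e in self._edges.items() if name not in (e.source, e.target)}
        return self

    def remove_edge(self, source: str, target: str, edge_type: int) -> "Network":
        if not self.directed:
            source, target = sorted((source, target))
        key = (source, target, edge_type)
        if key not in self._edges:
            raise MedusaError(f"no edge ({source!r}, {target!r}) with type {edge_type}")
        del self._edges[key]
        return self

    # -- copying / equality ------------------------------------------------

    def copy(self) -> "Network":
        net = Network(directed=self.directed, background_image=self.background_image)
        net._nodes = dict(self._nodes)
        net._edges = dict(self._edges)
        net._collapsed = _copy.deepcopy(self._collapsed)
        return net

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.directed == other.directed
            and self.background_image == other.background_image
            and self._nodes == other._nodes
            and self._edges == other._edges
            and set(self._collapsed) == set(other._collapsed)
        )

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"<Network {kind}, {self.n_nodes} nodes, {self.n_edges} edges>"


# ---------------------------------------------------------------------------
# Functional operations


def filter_edges(net: Network, min_weight: float, types: Optional[Iterable[int]] = None) -> Network:
    """Copy of *net* keeping edges with ``weight >= min_weight`` (and, when
    given, ``edge_type`` in *types*).  Nodes are never dropped."""
    if not (0.0 <= min_weight <= 1.0):
        raise ValueError(f"min_weight must lie in [0, 1], got {min_weight!r}")
    type_set = None if types is None else set(types)
    out = net.copy()
    out._edges = {
        k: e
        for k, e in net._edges.items()
        if e.weight >= min_weight and (type_set is None or e.edge_type in type_set)
    }
    return out


def isolate(net: Network, focus: Iterable[str]) -> list[Edge]:
    """Edges with at least one endpoint in *focus* (edge isolation)."""
    focus = set(focus)
    for name in focus:
        if not net.has_node(name):
            raise UnknownNodeError(f"unknown node {name!r}")
    return [e for e in net.edges if e.source in focus or e.target in focus]


def search(net: Network, pattern: str, fields: Iterable[str] = ("name",)) -> set[str]:
    """Names of nodes whose *name* and/or *annotation* contains a match of
    the regular expression *pattern* (substring semantics)."""
    fields = set(fields)
    unknown = fields - {"name", "annotation"}
    if unknown:
        raise ValueError(f"unknown search fields: {sorted(unknown)}")
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise InvalidPatternError(f"invalid regular expression {pattern!r}: {exc}") from exc
    hits = set()
    for node in net.nodes:
        if "name" in fields and rx.search(node.name):
            hits.add(node.name)
        elif "annotation" in fields and node.annotation is not None and rx.search(node.annotation):
            hits.add(node.name)
    return hits


def collapse(net: Network, group: Iterable[str], meta_name: str) -> Network:
    """Merge *group* into a single meta-node named *meta_name*.

    Parallel external edges are aggregated per (neighbour, edge_type) —
    per direction for directed networks — keeping the maximum weight, so
    the strongest evidence survives and weights stay in [0, 1].
    Intra-group edges are recorded for :func:`expand`, not shown.
    """
    group = set(group)
    if len(group) < 2:
        raise MedusaError("collapse needs a group of at least 2 nodes")
    for name in group:
        if not net.has_node(name):
            raise UnknownNodeError(f"unknown node {name!r}")
    if net.has_node(meta_name):
        raise DuplicateNodeError(f"meta-node name {meta_name!r} is already in use")

    members = tuple(net.node(n) for n in sorted(group))
    touched = tuple(e for e in net.edges if e.source in group or e.target in group)

    out = net.copy()
    for name in group:
        out.remove_node(name)

    xs = [n.x for n in members if n.x is not None]
    ys = [n.y for n in members if n.y is not None]
    meta = Node(
        name=meta_name,
        x=sum(xs) / len(xs) if xs else None,
        y=sum(ys) / len(ys) if ys else None,
        shape="hexagon",
    )
    out.add_node(meta)

    # aggregate external connections
    agg: dict[tuple, float] = {}
    for e in touched:
        if e.source in group and e.target in group:
            continue
        neighbour = e.target if e.source in group else e.source
        outgoing = e.source in group  # meaningful only for directed nets
        key = (neighbour, e.edge_type, outgoing if net.directed else True)
        agg[key] = max(agg.get(key, 0.0), e.weight)
    for (neighbour, etype, outgoing), w in sorted(agg.items()):
        src, tgt = (meta_name, neighbour) if outgoing else (neighbour, meta_name)
        out.add_edge(Edge(source=src, target=tgt, edge_type=etype, weight=w))

    out._collapsed[meta_name] = CollapseRecord(meta_name=meta_name, members=members, edges=touched)
    return out


def expand(net: Network, meta_name: str) -> Network:
    """Undo a :func:`collapse`, restoring members and their edges exactly."""
    record = net._collapsed.get(meta_name)
    if record is None:
        raise MedusaError(f"{meta_name!r} is not a collapsed meta-node")
    out = net.copy()
    out.remove_node(meta_name)
    del out._collapsed[meta_name]
    for node in record.members:
        out.add_node(node)
    for edge in record.edges:
        out.add_edge(edge)
    return out


# ---------------------------------------------------------------------------
# Statistics


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_pairs: int
    per_type_counts: dict[int, int]
    degree: dict[str, int]
    min_degree: float
    max_degree: float
    mean_degree: float
    n_components: int
    density: float


def connected_components(net: Network) -> list[set[str]]:
    """Connected components ignoring edge direction, sorted by smallest member."""
    parent = {n: n for n in net.node_names}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for e in net.edges:
        ra, rb = find(e.source), find(e.target)
        if ra != rb:
            parent[rb] = ra
    groups: dict[str, set[str]] = {}
    for n in net.node_names:
        groups.setdefault(find(n), set()).add(n)
    return sorted(groups.values(), key=min)


def stats(net: Network) -> NetworkStats:
    """Simple network statistics: counts, degrees, components, density.

    Degree counts incident edge records under the undirected interpretation,
    so the degree sum always equals twice the number of edge records.
    """
    degree = {n: 0 for n in net.node_names}
    per_type: dict[int, int] = {}
    pairs = set()
    for e in net.edges:
        degree[e.source] += 1
        degree[e.target] += 1
        per_type[e.edge_type] = per_type.get(e.edge_type, 0) + 1
        pairs.add(e.pair())
    n = net.n_nodes
    degs = list(degree.values())
    return NetworkStats(
        n_nodes=n,
        n_edges=net.n_edges,
        n_pairs=len(pairs),
        per_type_counts=dict(sorted(per_type.items())),
        degree=degree,
        min_degree=float(min(degs)) if degs else 0.0,
        max_degree=float(max(degs)) if degs else 0.0,
        mean_degree=(sum(degs) / n) if n else 0.0,
        n_components=len(connected_components(net)) if n else 0,
        density=(len(pairs) / (n * (n - 1) / 2)) if n >= 2 else 0.0,
    )
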