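"""Synthetic network and point-cloud generators, plus minimal reference
parsers for the interchange formats.

Every generator is deterministic given its :class:`FixtureSpec` (one
explicit RNG stream per spec, no global state) and emits its ground truth
(planted labels, generating coordinates) alongside the network, so
clustering and embedding results can be scored without external data.

The reference parsers deliberately share no code with the exporters in
:mod:`pymedusa.interchange`; they exist so exports can be checked by an
independent route.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Edge, Network, Node
from .errors import ParseError
from .layouts import LayoutResult

KINDS = (
    "random_graph",
    "planted_partition",
    "tree",
    "cycle",
    "multi_edge",
    "gaussian_clouds",
    "planar_points",
)


@dataclass
class FixtureSpec:
    kind: str
    n: int = 10
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")


@dataclass
class Fixture:
    network: Network
    labels: Optional[dict[str, int]] = None  # planted cluster truth
    coords: Optional[LayoutResult] = None  # generating coordinates


def _name(i: int) -> str:
    return f"v{i:03d}"


def _empty_net(n: int, directed: bool = False) -> Network:
    net = Network(directed=directed)
    for i in range(n):
        net.add_node(Node(name=_name(i)))
    return net


def generate(spec: FixtureSpec) -> Fixture:
    """Build the fixture described by *spec* (see kind-specific helpers)."""
    rng = np.random.default_rng(spec.seed)
    fn = {
        "random_graph": _gen_random_graph,
        "planted_partition": _gen_planted_partition,
        "tree": _gen_tree,
        "cycle": _gen_cycle,
        "multi_edge": _gen_multi_edge,
        "gaussian_clouds": _gen_gaussian_clouds,
        "planar_points": _gen_planar_points,
    }[spec.kind]
    return fn(spec, rng)


def _check_prob(p: float, name: str = "p"):
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p}")


def _gen_random_graph(spec: FixtureSpec, rng) -> Fixture:
    """Erdos–Renyi G(n, p) with uniform edge weights."""
    p = spec.params.get("p", 0.1)
    _check_prob(p)
    net = _empty_net(spec.n, directed=spec.params.get("directed", False))
    for i in range(spec.n):
        for j in range(i + 1, spec.n):
            if rng.uniform() < p:
                net.add_edge(
                    Edge(source=_name(i), target=_name(j), weight=round(float(rng.uniform()), 6))
                )
    return Fixture(network=net)


def _gen_planted_partition(spec: FixtureSpec, rng) -> Fixture:
    """k blocks of block_size nodes; within-block edges with probability
    p_in, between-block with p_out; planted block labels returned."""
    k = spec.params.get("k", 2)
    block_size = spec.params.get("block_size", spec.n // max(k, 1))
    p_in = spec.params.get("p_in", 0.9)
    p_out = spec.params.get("p_out", 0.02)
    _check_prob(p_in, "p_in")
    _check_prob(p_out, "p_out")
    n = k * block_size
    net = _empty_net(n)
    labels = {_name(i): i // block_size for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if labels[_name(i)] == labels[_name(j)] else p_out
            if rng.uniform() < p:
                net.add_edge(Edge(source=_name(i), target=_name(j)))
    return Fixture(network=net, labels=labels)


def _gen_tree(spec: FixtureSpec, rng) -> Fixture:
    """Perfect b-ary tree of the given depth (directed root→leaves when
    params['directed'])."""
    depth = spec.params.get("depth", 2)
    b = spec.params.get("branching", 2)
    n = (b ** (depth + 1) - 1) // (b - 1) if b > 1 else depth + 1
    net = _empty_net(n, directed=spec.params.get("directed", False))
    for i in range(1, n):
        parent = (i - 1) // b
        net.add_edge(Edge(source=_name(parent), target=_name(i)))
    return Fixture(network=net)


def _gen_cycle(spec: FixtureSpec, rng) -> Fixture:
    net = _empty_net(spec.n, directed=spec.params.get("directed", False))
    for i in range(spec.n):
        if spec.n >= 3 or (spec.n == 2 and i == 0):
            net.add_edge(Edge(source=_name(i), target=_name((i + 1) % spec.n)))
    return Fixture(network=net)


def _gen_multi_edge(spec: FixtureSpec, rng) -> Fixture:
    """G(n, p) where each connected pair carries 1..max_types parallel
    typed edges with uniform weights."""
    p = spec.params.get("p", 0.2)
    max_types = spec.params.get("max_types", 8)
    _check_prob(p)
    if not (1 <= max_types <= 8):
        raise ValueError("max_types must lie in 1..8")
    net = _empty_net(spec.n)
    for i in range(spec.n):
        for j in range(i + 1, spec.n):
            if rng.uniform() < p:
                n_types = int(rng.integers(1, max_types + 1))
                types = rng.choice(8, size=n_types, replace=False) + 1
                for t in sorted(int(t) for t in types):
                    net.add_edge(
                        Edge(
                            source=_name(i),
                            target=_name(j),
                            edge_type=t,
                            weight=round(float(rng.uniform()), 6),
                        )
                    )
    return Fixture(network=net)


def _gen_gaussian_clouds(spec: FixtureSpec, rng) -> Fixture:
    """k isotropic Gaussian clouds in the unit square; adjacent cloud
    centers sit `separation`·sigma apart; planted labels and true
    coordinates are returned (no edges)."""
    k = spec.params.get("k", 2)
    sigma = spec.params.get("sigma", 0.03)
    separation = spec.params.get("separation", 10.0)
    n = spec.n
    d = separation * sigma
    if k == 1:
        centers = [(0.5, 0.5)]
    elif k == 2:
        centers = [(0.5 - d / 2, 0.5), (0.5 + d / 2, 0.5)]
    else:
        radius = d / (2 * math.sin(math.pi / k))
        centers = [
            (0.5 + radius * math.cos(2 * math.pi * i / k),
             0.5 + radius * math.sin(2 * math.pi * i / k))
            for i in range(k)
        ]
    net = Network()
    labels: dict[str, int] = {}
    coords: dict[str, tuple[float, float]] = {}
    for i in range(n):
        lab = i % k
        cx, cy = centers[lab]
        x = float(np.clip(rng.normal(cx, sigma), 0, 1))
        y = float(np.clip(rng.normal(cy, sigma), 0, 1))
        name = _name(i)
        net.add_node(Node(name=name, x=x, y=y))
        labels[name] = lab
        coords[name] = (x, y)
    layout = LayoutResult(coords=coords, algorithm="random", seed=spec.seed)
    return Fixture(network=net, labels=labels, coords=layout)


def _gen_planar_points(spec: FixtureSpec, rng) -> Fixture:
    """n uniform points in the unit square (isolated nodes with true
    coordinates), for embedding-recovery checks."""
    net = Network()
    coords = {}
    for i in range(spec.n):
        x, y = (float(v) for v in rng.uniform(0, 1, size=2))
        net.add_node(Node(name=_name(i), x=x, y=y))
        coords[_name(i)] = (x, y)
    return Fixture(network=net, coords=LayoutResult(coords=coords, algorithm="random", seed=spec.seed))


def random_network(seed: int, n_max: int = 12) -> Network:
    """A random network exercising the full attribute surface (colors,
    shapes, coordinates, annotations with spaces and quotes, URLs,
    orientations, parallel typed edges, directedness) — the workhorse for
    persistence round-trip checks."""
    from .core import ORIENTATIONS, SHAPES

    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, n_max))
    net = Network(directed=bool(rng.integers(2)))
    names = [f"g{i:02d}" for i in range(n)]
    for i, name in enumerate(names):
        kwargs = {}
        if rng.uniform() < 0.5:
            kwargs["color"] = tuple(int(v) for v in rng.integers(0, 256, 3))
        if rng.uniform() < 0.5:
            kwargs["shape"] = SHAPES[rng.integers(len(SHAPES))]
        if rng.uniform() < 0.5:
            kwargs["x"] = round(float(rng.uniform()), 6)
            kwargs["y"] = round(float(rng.uniform()), 6)
        if rng.uniform() < 0.4:
            kwargs["annotation"] = f'protein kinase "{i}" with spaces'
        if rng.uniform() < 0.3:
            kwargs["url"] = f"https://example.org/{name}"
        net.add_node(Node(name=name, **kwargs))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < 0.25:
                for t in range(1, int(rng.integers(1, 4)) + 1):
                    net.add_edge(
                        Edge(
                            source=names[i],
                            target=names[j],
                            edge_type=t,
                            weight=round(float(rng.uniform()), 6),
                            orientation=ORIENTATIONS[rng.integers(len(ORIENTATIONS))],
                        )
                    )
    return net


def random_document(seed: int):
    """A random :class:`~pymedusa.io.MedusaDocument`, sometimes carrying
    layout and clustering session state."""
    from .clustering import Clustering
    from .colors import cluster_color
    from .io import MedusaDocument

    rng = np.random.default_rng(seed + 10_000)
    net = random_network(seed)
    doc = MedusaDocument(network=net)
    names = net.node_names
    if rng.uniform() < 0.5:
        doc.layout = LayoutResult(
            coords={
                m: (round(float(rng.uniform()), 6), round(float(rng.uniform()), 6))
                for m in names
            },
            algorithm="random",
            seed=int(rng.integers(100)),
        )
    if rng.uniform() < 0.5:
        k = int(rng.integers(1, max(2, len(names))))
        assignment = {m: int(rng.integers(k)) for m in names}
        used = sorted(set(assignment.values()))
        relabel = {old: new for new, old in enumerate(used)}
        assignment = {m: relabel[c] for m, c in assignment.items()}
        k = len(used)
        doc.clustering = Clustering(
            assignment=assignment,
            k=k,
            colors={c: cluster_color(c) for c in range(k)},
            method="predefined",
        )
    return doc


# ---------------------------------------------------------------------------
# independent minimal re-parsers (test oracles for the exporters)


def parse_pajek(text: str) -> tuple[int, int]:
    """Count (n_nodes, n_edge_records) in Pajek NET text."""
    n_vertices = None
    n_edges = 0
    mode = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            try:
                n_vertices = int(line.split()[1])
            except (IndexError, ValueError):
                raise ParseError("malformed *Vertices header", line=lineno)
            mode = "vertices"
        elif low in ("*edges", "*arcs"):
            mode = "edges"
        elif mode == "edges":
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"malformed edge line {line!r}", line=lineno)
            int(fields[0]), int(fields[1])
            n_edges += 1
        elif mode != "vertices":
            raise ParseError(f"unexpected line {line!r}", line=lineno)
    if n_vertices is None:
        raise ParseError("no *Vertices header")
    return n_vertices, n_edges


def parse_sif(text: str) -> tuple[int, int]:
    """Count (n_nodes, n_edge_records) in SIF text."""
    nodes = set()
    n_edges = 0
    for lineno, raw in enumerate(text.splitlines(), 1):
        fields = raw.split()
        if not fields:
            continue
        if len(fields) == 1:
            nodes.add(fields[0])
        elif len(fields) >= 3:
            src, _rel, targets = fields[0], fields[1], fields[2:]
            nodes.add(src)
            nodes.update(targets)
            n_edges += len(targets)
        else:
            raise ParseError(f"malformed SIF line {raw!r}", line=lineno)
    return len(nodes), n_edges


_DOT_ID = r'(?:"(?:[^"\\]|\\.)*"|[A-Za-z_][A-Za-z0-9_]*|\d+)'


def parse_dot(text: str) -> tuple[int, int]:
    """Grammar-level check and entity count for the DOT dialect the
    exporter emits: a graph/digraph block of node and edge statements."""
    header = re.match(r"\s*(strict\s+)?(graph|digraph)\s+" + _DOT_ID + r"?\s*\{", text)
    if not header:
        raise ParseError("missing graph/digraph header")
    body = text[header.end():]
    close = body.rfind("}")
    if close < 0:
        raise ParseError("missing closing brace")
    if body[close + 1:].strip():
        raise ParseError("content after closing brace")
    body = body[:close]
    nodes = set()
    n_edges = 0
    stmt_re = re.compile(
        rf"^\s*(?P<a>{_DOT_ID})\s*(?:(?P<op>--|->)\s*(?P<b>{_DOT_ID}))?\s*(?:\[(?P<attrs>[^\]]*)\])?\s*;\s*$"
    )
    for lineno, raw in enumerate(body.splitlines(), 2):
        if not raw.strip():
            continue
        m = stmt_re.match(raw)
        if not m:
            raise ParseError(f"malformed DOT statement {raw.strip()!r}", line=lineno)

        def unquote(token: str) -> str:
            if token.startswith('"'):
                return token[1:-1].replace('\\"', '"').replace("\\\\", "\\")
            return token

        nodes.add(unquote(m.group("a")))
        if m.group("op"):
            nodes.add(unquote(m.group("b")))
            n_edges += 1
    return len(nodes), n_edges
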