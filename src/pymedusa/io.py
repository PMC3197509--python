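"""Reader/writer for the medusa flat-file format and session state.

The graph file dialect (normative grammar in FORMAT.md):

* an optional ``*directed`` header line marks the network as directed;
* a ``*edges`` section with lines ``SRC TGT c:K [conf:W] [o:ORIENT]``
  (type K in 1..8, confidence W in [0,1], orientation up/down/straight);
* a ``*nodes`` section with lines
  ``NAME [c:R,G,B|#RRGGBB] [s:SHAPE] [x:F] [y:F] [a:"text"] [u:URL]``;
* lines whose first non-blank character is ``#`` are comments.

Unknown ``key:value`` attribute tokens are preserved verbatim and
re-emitted on write.  Edges may name nodes that are never declared in the
``*nodes`` section; such nodes are auto-created with default attributes
and a warning.  The writer emits a canonical form (sorted nodes and
edges, fixed attribute order), which makes write∘read idempotent.

Session state beyond the graph itself — a layout, a clustering, a
background image path — is stored in a companion sidecar file
``<path>.session`` with simple ``key: value`` lines, keeping the graph
file interoperable.
"""

from __future__ import annotations

import os
import shlex
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .clustering import Clustering
from .colors import parse_color
from .core import DEFAULT_NODE_COLOR, Edge, Network, Node
from .errors import ParseError
from .layouts import LayoutResult

_EDGE_KEYS = {"c", "conf", "o"}
_NODE_KEYS = {"c", "s", "x", "y", "a", "u"}


@dataclass
class MedusaDocument:
    """A network plus optional session state (layout, clustering,
    background image)."""

    network: Network
    layout: Optional[LayoutResult] = None
    clustering: Optional[Clustering] = None
    background_image: Optional[str] = None

    def __post_init__(self):
        if self.background_image is None:
            self.background_image = self.network.background_image

    def __eq__(self, other):
        if not isinstance(other, MedusaDocument):
            return NotImplemented
        return (
            self.network == other.network
            and _layout_eq(self.layout, other.layout)
            and _clustering_eq(self.clustering, other.clustering)
            and self.background_image == other.background_image
        )


def _layout_eq(a: Optional[LayoutResult], b: Optional[LayoutResult]) -> bool:
    if a is None or b is None:
        return a is b
    return a.coords == b.coords and a.algorithm == b.algorithm and a.seed == b.seed


def _clustering_eq(a: Optional[Clustering], b: Optional[Clustering]) -> bool:
    if a is None or b is None:
        return a is b
    return (
        a.assignment == b.assignment
        and a.k == b.k
        and a.method == b.method
        and a.exemplars == b.exemplars
    )


# ---------------------------------------------------------------------------
# reading


def _tokenize(line: str, lineno: int) -> list[str]:
    try:
        return shlex.split(line, comments=False, posix=True)
    except ValueError as exc:
        raise ParseError(f"bad quoting: {exc}", line=lineno) from exc


def _split_attr(token: str, lineno: int) -> tuple[str, str]:
    if ":" not in token:
        raise ParseError(f"malformed attribute {token!r} (expected key:value)", line=lineno)
    key, value = token.split(":", 1)
    return key, value


def read_medusa(path) -> MedusaDocument:
    """Parse a medusa graph file (and its ``.session`` sidecar if present).

    Every non-empty, non-comment line either populates the model or raises
    a :class:`ParseError` carrying its line number.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    directed = False
    section = None
    seen_edges_header = False
    seen_nodes_header = False
    edges: list[tuple[int, Edge]] = []
    declared: dict[str, Node] = {}

    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower() == "*directed":
            directed = True
            continue
        if line.lower() == "*edges":
            section = "edges"
            seen_edges_header = True
            continue
        if line.lower() == "*nodes":
            section = "nodes"
            seen_nodes_header = True
            continue
        if line.startswith("*"):
            raise ParseError(f"unknown section header {line!r}", line=lineno)
        if section is None:
            raise ParseError("content before the first section header", line=lineno)
        tokens = _tokenize(line, lineno)
        if section == "edges":
            edges.append((lineno, _parse_edge_line(tokens, lineno)))
        else:
            node = _parse_node_line(tokens, lineno)
            declared[node.name] = node

    if not (seen_edges_header and seen_nodes_header):
        missing = "*edges" if not seen_edges_header else "*nodes"
        raise ParseError(f"missing required section header {missing!r}")

    net = Network(directed=directed)
    for node in declared.values():
        net.add_node(node)
    auto_created = []
    for lineno, edge in edges:
        for end in (edge.source, edge.target):
            if not net.has_node(end):
                net.add_node(Node(name=end))
                auto_created.append(end)
        try:
            net.add_edge(edge)
        except Exception as exc:
            raise ParseError(str(exc), line=lineno) from exc
    if auto_created:
        warnings.warn(
            f"auto-created {len(auto_created)} node(s) referenced only by edges: "
            + ", ".join(sorted(set(auto_created)))
        )

    doc = MedusaDocument(network=net)
    sidecar = f"{path}.session"
    if os.path.exists(sidecar):
        _read_session(doc, sidecar)
    return doc


def _parse_edge_line(tokens: list[str], lineno: int) -> Edge:
    if len(tokens) < 2:
        raise ParseError("edge line needs at least SRC and TGT", line=lineno)
    src, tgt = tokens[0], tokens[1]
    etype, weight, orient = 1, 1.0, "auto"
    extras = []
    for token in tokens[2:]:
        key, value = _split_attr(token, lineno)
        try:
            if key == "c":
                etype = int(value)
            elif key == "conf":
                weight = float(value)
            elif key == "o":
                orient = value
            else:
                extras.append(token)
        except ValueError as exc:
            raise ParseError(f"bad value for {key!r}: {value!r}", line=lineno) from exc
    try:
        return Edge(
            source=src, target=tgt, edge_type=etype, weight=weight,
            orientation=orient, extras=tuple(extras),
        )
    except ValueError as exc:
        raise ParseError(str(exc), line=lineno) from exc


def _parse_node_line(tokens: list[str], lineno: int) -> Node:
    name = tokens[0]
    attrs = {"color": DEFAULT_NODE_COLOR, "shape": "circle"}
    extras = []
    for token in tokens[1:]:
        key, value = _split_attr(token, lineno)
        try:
            if key == "c":
                attrs["color"] = parse_color(value)
            elif key == "s":
                attrs["shape"] = value
            elif key == "x":
                attrs["x"] = float(value)
            elif key == "y":
                attrs["y"] = float(value)
            elif key == "a":
                attrs["annotation"] = value
            elif key == "u":
                attrs["url"] = value
            else:
                extras.append(token)
        except ValueError as exc:
            raise ParseError(f"bad value for {key!r}: {value!r}", line=lineno) from exc
    try:
        return Node(name=name, extras=tuple(extras), **attrs)
    except ValueError as exc:
        raise ParseError(str(exc), line=lineno) from exc


# ---------------------------------------------------------------------------
# writing


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _edge_line(edge: Edge) -> str:
    parts = [edge.source, edge.target, f"c:{edge.edge_type}", f"conf:{_fmt_float(edge.weight)}"]
    if edge.orientation != "auto":
        parts.append(f"o:{edge.orientation}")
    parts.extend(edge.extras)
    return " ".join(parts)


def _node_line(node: Node) -> str:
    parts = [node.name, "c:{},{},{}".format(*node.color), f"s:{node.shape}"]
    if node.x is not None:
        parts.append(f"x:{_fmt_float(node.x)}")
    if node.y is not None:
        parts.append(f"y:{_fmt_float(node.y)}")
    if node.annotation is not None:
        escaped = node.annotation.replace("\\", "\\\\").replace('"', '\\"')
        parts.append(f'a:"{escaped}"')
    if node.url is not None:
        parts.append(f"u:{node.url}")
    parts.extend(node.extras)
    return " ".join(parts)


def write_medusa(doc: MedusaDocument, path) -> None:
    """Write the canonical form of *doc*: nodes lexicographic, edges sorted
    by (source, target, type).  Session state goes to ``<path>.session``;
    a stale sidecar is removed when the document carries no session."""
    net = doc.network
    out = []
    if net.directed:
        out.append("*directed")
    out.append("*edges")
    out.extend(_edge_line(e) for e in net.edges)
    out.append("*nodes")
    out.extend(_node_line(n) for n in net.nodes)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")

    sidecar = f"{path}.session"
    if doc.layout is not None or doc.clustering is not None or doc.background_image is not None:
        _write_session(doc, sidecar)
    elif os.path.exists(sidecar):
        os.remove(sidecar)


# ---------------------------------------------------------------------------
# session sidecar


def _write_session(doc: MedusaDocument, path) -> None:
    lines = []
    if doc.background_image is not None:
        lines.append(f"background: {doc.background_image}")
    if doc.layout is not None:
        lines.append(f"layout.algorithm: {doc.layout.algorithm}")
        if doc.layout.seed is not None:
            lines.append(f"layout.seed: {doc.layout.seed}")
        for name in sorted(doc.layout.coords):
            x, y = doc.layout.coords[name]
            lines.append(f"layout.coord: {name} {_fmt_float(x)} {_fmt_float(y)}")
    if doc.clustering is not None:
        cl = doc.clustering
        lines.append(f"cluster.method: {cl.method}")
        lines.append(f"cluster.k: {cl.k}")
        for name in sorted(cl.assignment):
            lines.append(f"cluster.assign: {name} {cl.assignment[name]}")
        if cl.exemplars:
            for cid in sorted(cl.exemplars):
                lines.append(f"cluster.exemplar: {cid} {cl.exemplars[cid]}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_session(doc: MedusaDocument, path) -> None:
    coords: dict[str, tuple[float, float]] = {}
    layout_algo = None
    layout_seed = None
    assignment: dict[str, int] = {}
    exemplars: dict[int, str] = {}
    method = None
    k = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError(f"malformed session line {line!r}", line=lineno)
            key, value = line.split(":", 1)
            key, value = key.strip(), value.strip()
            try:
                if key == "background":
                    doc.background_image = value
                    doc.network.background_image = value
                elif key == "layout.algorithm":
                    layout_algo = value
                elif key == "layout.seed":
                    layout_seed = int(value)
                elif key == "layout.coord":
                    name, x, y = value.split()
                    coords[name] = (float(x), float(y))
                elif key == "cluster.method":
                    method = value
                elif key == "cluster.k":
                    k = int(value)
                elif key == "cluster.assign":
                    name, cid = value.split()
                    assignment[name] = int(cid)
                elif key == "cluster.exemplar":
                    cid, name = value.split()
                    exemplars[int(cid)] = name
                else:
                    raise ParseError(f"unknown session key {key!r}", line=lineno)
            except (ValueError, TypeError) as exc:
                raise ParseError(f"bad session value for {key!r}: {value!r}", line=lineno) from exc
    if layout_algo is not None:
        doc.layout = LayoutResult(coords=coords, algorithm=layout_algo, seed=layout_seed)
    if method is not None:
        from .colors import cluster_color

        k = k if k is not None else (max(assignment.values()) + 1 if assignment else 0)
        doc.clustering = Clustering(
            assignment=assignment,
            k=k,
            colors={c: cluster_color(c) for c in range(k)},
            method=method,
            exemplars=exemplars or None,
        )
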