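"""Exporters to Pajek NET, Cytoscape SIF, and GraphViz DOT.

All exporters are deterministic: the same document always yields
byte-identical text.  Vertex/node order is lexicographic; parallel typed
edges become one output line each.  The registry at the bottom lets new
dialects be plugged in without touching the CLI.
"""

from __future__ import annotations

from typing import Optional

from .colors import to_hex
from .core import Network
from .layouts import LayoutResult

def _coord(x: float) -> str:
    return f"{x:.6g}"


_DOT_SHAPES = {
    "circle": "ellipse",
    "rectangle": "box",
    "triangle": "triangle",
    "diamond": "diamond",
    "hexagon": "hexagon",
}


def export_pajek(net: Network, layout: Optional[LayoutResult] = None) -> str:
    """Pajek NET text: ``*Vertices N`` with 1-based ids and quoted labels
    (plus x y coordinates when a layout is given), then ``*Edges`` for
    undirected or ``*Arcs`` for directed networks, one ``i j w`` line per
    edge record."""
    names = net.node_names
    ids = {name: i + 1 for i, name in enumerate(names)}
    lines = [f"*Vertices {len(names)}"]
    for name in names:
        line = f'{ids[name]} "{name}"'
        if layout is not None and name in layout:
            x, y = layout.coords[name]
            line += f" {_coord(x)} {_coord(y)}"
        lines.append(line)
    lines.append("*Arcs" if net.directed else "*Edges")
    for e in net.edges:
        lines.append(f"{ids[e.source]} {ids[e.target]} {e.weight!r}")
    return "\n".join(lines) + "\n"


def export_sif(net: Network) -> str:
    """Cytoscape SIF text: one ``SRC typeK TGT`` line per edge record
    (relation token = ``type`` + edge type); isolated nodes appear as
    single-column lines.  SIF has no weight column, so weights are
    dropped."""
    connected = set()
    lines = []
    for e in net.edges:
        lines.append(f"{e.source} type{e.edge_type} {e.target}")
        connected.update((e.source, e.target))
    for name in net.node_names:
        if name not in connected:
            lines.append(name)
    return "\n".join(lines) + ("\n" if lines else "")


def _dot_quote(name: str) -> str:
    return '"' + name.replace("\\", "\\\\").replace('"', '\\"') + '"'


def export_dot(
    net: Network,
    layout: Optional[LayoutResult] = None,
    styles: Optional[dict] = None,
) -> str:
    """GraphViz DOT text: ``graph``/``digraph`` per directedness, node
    statements carrying fill color and shape (and a ``pos`` attribute when
    a layout is given), one edge statement per edge record.  All names are
    quoted, so reserved characters are escaped, never mangled."""
    styles = styles or {}
    op = "->" if net.directed else "--"
    lines = ["digraph medusa {" if net.directed else "graph medusa {"]
    for node in net.nodes:
        attrs = [
            f'fillcolor="{to_hex(node.color)}"',
            "style=filled",
            f"shape={_DOT_SHAPES[node.shape]}",
        ]
        if layout is not None and node.name in layout:
            x, y = layout.coords[node.name]
            attrs.append(f'pos="{_coord(x)},{_coord(y)}!"')
        for key, value in sorted(styles.get(node.name, {}).items()):
            attrs.append(f'{key}="{value}"')
        lines.append(f"  {_dot_quote(node.name)} [{', '.join(attrs)}];")
    for e in net.edges:
        attrs = f'[label="type{e.edge_type}", weight={e.weight!r}]'
        lines.append(f"  {_dot_quote(e.source)} {op} {_dot_quote(e.target)} {attrs};")
    lines.append("}")
    return "\n".join(lines) + "\n"


#: exporter registry: format name -> callable(net, layout=None) -> text
EXPORTERS = {
    "pajek": lambda net, layout=None: export_pajek(net, layout),
    "sif": lambda net, layout=None: export_sif(net),
    "dot": lambda net, layout=None: export_dot(net, layout),
}
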