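"""Deterministic static rendering to SVG and PNG.

Visual conventions: each of the eight edge types keeps a unique fixed
color; edge confidence maps to line opacity (0.15 + 0.85·w), so faint
lines mean weak evidence on any background; parallel edges between a pair
fan out as quadratic Bezier curves with symmetric perpendicular offsets
(an odd count keeps one straight line); directed edges carry an arrowhead
at 80% of the path; cluster colors override node colors when a clustering
is supplied; an optional raster image is stretched behind the canvas.

``render_svg`` is a pure function of its inputs: identical inputs yield
byte-identical SVG text.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Optional
from xml.sax.saxutils import escape, quoteattr

from .colors import EDGE_TYPE_PALETTE, to_hex
from .core import Edge, Network, isolate
from .errors import MedusaError
from .layouts import LayoutResult


@dataclass
class StyleConfig:
    """Rendering options; defaults reproduce the standard look."""

    canvas: tuple[int, int] = (1000, 1000)
    type_palette: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(EDGE_TYPE_PALETTE)
    )
    node_radius: float = 8.0
    show_labels: bool = True
    focus: Optional[frozenset] = None
    background_image: Optional[str] = None
    arrowheads: bool = True
    bezier_offset_fraction: float = 0.03  # of canvas width, per rank

    def __post_init__(self):
        if len(set(self.type_palette.values())) != len(self.type_palette):
            raise ValueError("edge type colors must be pairwise distinct")


def weight_to_alpha(weight: float) -> float:
    """Linear confidence→opacity map; even weight 0 stays faintly visible."""
    return 0.15 + 0.85 * weight


# ---------------------------------------------------------------------------
# geometry


def _edge_groups(edges: Iterable[Edge]) -> dict[tuple[str, str], list[Edge]]:
    groups: dict[tuple[str, str], list[Edge]] = {}
    for e in edges:
        groups.setdefault(e.pair(), []).append(e)
    for group in groups.values():
        group.sort(key=lambda e: (e.source, e.target, e.edge_type))
    return groups


def _perp_up(p1, p2) -> tuple[float, float]:
    """Unit perpendicular of the segment pointing visually upward
    (negative y in screen coordinates); left for vertical segments."""
    dx, dy = p2[0] - p1[0], p2[1] - p1[1]
    norm = math.hypot(dx, dy) or 1.0
    px, py = -dy / norm, dx / norm
    if py > 0 or (py == 0 and px > 0):
        px, py = -px, -py
    return px, py


def edge_paths(
    net: Network, layout: LayoutResult, style: StyleConfig
) -> list[tuple[Edge, tuple, tuple, Optional[tuple]]]:
    """Resolved drawing geometry: (edge, p1, p2, control-or-None) per edge
    record, in deterministic order, in pixel coordinates."""
    W, H = style.canvas
    edges = net.edges
    if style.focus is not None:
        keep = {(e.source, e.target, e.edge_type) for e in isolate(net, style.focus)}
        edges = [e for e in edges if (e.source, e.target, e.edge_type) in keep]
    for e in edges:
        for end in (e.source, e.target):
            if end not in layout:
                raise MedusaError(f"layout has no coordinates for node {end!r}")
    out = []
    for pair, group in sorted(_edge_groups(edges).items()):
        p1 = (layout.coords[pair[0]][0] * W, layout.coords[pair[0]][1] * H)
        p2 = (layout.coords[pair[1]][0] * W, layout.coords[pair[1]][1] * H)
        up = _perp_up(p1, p2)
        m = len(group)
        for i, e in enumerate(group):
            rank = i - (m - 1) / 2  # symmetric around 0; odd m keeps one straight
            if e.orientation == "straight":
                rank = 0.0
            elif e.orientation == "up":  # positive rank bows along `up`
                rank = abs(rank) or 1.0
            elif e.orientation == "down":
                rank = -abs(rank) or -1.0
            a, b = (p1, p2) if (e.source, e.target) == pair else (p2, p1)
            if rank == 0.0:
                out.append((e, a, b, None))
            else:
                offset = style.bezier_offset_fraction * W * rank
                mid = ((a[0] + b[0]) / 2, (a[1] + b[1]) / 2)
                # positive rank bows along +up*offset; negative rank mirrors it
                ctrl = (mid[0] + up[0] * offset, mid[1] + up[1] * offset)
                out.append((e, a, b, ctrl))
    return out


def _point_on_path(p1, p2, ctrl, t: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Point and tangent at parameter t of a segment/quadratic Bezier."""
    if ctrl is None:
        pt = (p1[0] + t * (p2[0] - p1[0]), p1[1] + t * (p2[1] - p1[1]))
        tan = (p2[0] - p1[0], p2[1] - p1[1])
    else:
        u = 1 - t
        pt = (
            u * u * p1[0] + 2 * u * t * ctrl[0] + t * t * p2[0],
            u * u * p1[1] + 2 * u * t * ctrl[1] + t * t * p2[1],
        )
        tan = (
            2 * u * (ctrl[0] - p1[0]) + 2 * t * (p2[0] - ctrl[0]),
            2 * u * (ctrl[1] - p1[1]) + 2 * t * (p2[1] - ctrl[1]),
        )
    norm = math.hypot(*tan) or 1.0
    return pt, (tan[0] / norm, tan[1] / norm)


def _arrowhead_points(p1, p2, ctrl) -> list[tuple[float, float]]:
    (px, py), (tx, ty) = _point_on_path(p1, p2, ctrl, 0.8)
    nx, ny = -ty, tx
    tip = (px + 6 * tx, py + 6 * ty)
    left = (px - 4 * tx + 3.5 * nx, py - 4 * ty + 3.5 * ny)
    right = (px - 4 * tx - 3.5 * nx, py - 4 * ty - 3.5 * ny)
    return [tip, left, right]


def _f(x: float) -> str:
    return f"{x:.2f}"


# ---------------------------------------------------------------------------
# SVG


def render_svg(
    net: Network,
    layout: LayoutResult,
    style: Optional[StyleConfig] = None,
    clustering=None,
) -> str:
    """Render to SVG 1.1 text.  Draw order: background, edges, nodes,
    labels.  Every node element carries its name in a ``data-name``
    attribute so drawings stay machine-inspectable."""
    style = style or StyleConfig()
    W, H = style.canvas
    for name in net.node_names:
        if name not in layout:
            raise MedusaError(f"layout has no coordinates for node {name!r}")
    background = style.background_image or net.background_image
    if background is not None and not os.path.exists(background):
        raise MedusaError(f"background image not readable: {background!r}")

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{W}" height="{H}" '
        f'viewBox="0 0 {W} {H}">',
        f'<rect width="{W}" height="{H}" fill="white"/>',
    ]
    if background is not None:
        parts.append(
            f'<image href={quoteattr(background)} x="0" y="0" width="{W}" height="{H}" '
            'preserveAspectRatio="none"/>'
        )

    for e, p1, p2, ctrl in edge_paths(net, layout, style):
        color = to_hex(style.type_palette[e.edge_type])
        alpha = weight_to_alpha(e.weight)
        if ctrl is None:
            d = f"M {_f(p1[0])} {_f(p1[1])} L {_f(p2[0])} {_f(p2[1])}"
        else:
            d = (
                f"M {_f(p1[0])} {_f(p1[1])} Q {_f(ctrl[0])} {_f(ctrl[1])} "
                f"{_f(p2[0])} {_f(p2[1])}"
            )
        parts.append(
            f'<path class="edge" data-type="{e.edge_type}" d="{d}" fill="none" '
            f'stroke="{color}" stroke-width="2" stroke-opacity="{alpha:.4f}"/>'
        )
        directed = net.directed if e.directed is None else e.directed
        if directed and style.arrowheads:
            pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in _arrowhead_points(p1, p2, ctrl))
            parts.append(
                f'<polygon class="arrowhead" points="{pts}" fill="{color}" '
                f'fill-opacity="{alpha:.4f}"/>'
            )

    r = style.node_radius
    for node in net.nodes:
        x, y = layout.coords[node.name]
        cx, cy = x * W, y * H
        color = node.color
        if clustering is not None and node.name in clustering.assignment:
            color = clustering.colors[clustering.assignment[node.name]]
        fill = to_hex(color)
        common = f'data-name={quoteattr(node.name)} fill="{fill}" stroke="#333333" stroke-width="1"'
        if node.shape == "circle":
            parts.append(f'<circle class="node" {common} cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(r)}"/>')
        elif node.shape == "rectangle":
            parts.append(
                f'<rect class="node" {common} x="{_f(cx - r)}" y="{_f(cy - r)}" '
                f'width="{_f(2 * r)}" height="{_f(2 * r)}"/>'
            )
        else:
            pts = " ".join(f"{_f(px)},{_f(py)}" for px, py in _shape_points(node.shape, cx, cy, r))
            parts.append(f'<polygon class="node" {common} points="{pts}"/>')

    if style.show_labels:
        for node in net.nodes:
            x, y = layout.coords[node.name]
            parts.append(
                f'<text class="label" x="{_f(x * W + r + 3)}" y="{_f(y * H + 4)}" '
                f'font-family="sans-serif" font-size="11">{escape(node.name)}</text>'
            )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _shape_points(shape: str, cx: float, cy: float, r: float) -> list[tuple[float, float]]:
    if shape == "triangle":
        return [(cx, cy - r), (cx - r, cy + r), (cx + r, cy + r)]
    if shape == "diamond":
        return [(cx, cy - r), (cx + r, cy), (cx, cy + r), (cx - r, cy)]
    if shape == "hexagon":
        return [
            (cx + r * math.cos(math.pi / 6 + i * math.pi / 3),
             cy + r * math.sin(math.pi / 6 + i * math.pi / 3))
            for i in range(6)
        ]
    raise ValueError(f"unknown shape {shape!r}")


# ---------------------------------------------------------------------------
# PNG (Pillow)


def render_png(
    net: Network,
    layout: LayoutResult,
    path,
    style: Optional[StyleConfig] = None,
    clustering=None,
) -> None:
    """Rasterise the same drawing to a PNG file via Pillow."""
    from PIL import Image, ImageDraw

    style = style or StyleConfig()
    W, H = style.canvas
    for name in net.node_names:
        if name not in layout:
            raise MedusaError(f"layout has no coordinates for node {name!r}")
    background = style.background_image or net.background_image

    img = Image.new("RGB", (W, H), (255, 255, 255))
    if background is not None:
        try:
            bg = Image.open(background).convert("RGB").resize((W, H))
        except OSError as exc:
            raise MedusaError(f"background image not readable: {background!r}") from exc
        img.paste(bg, (0, 0))

    overlay = Image.new("RGBA", (W, H), (0, 0, 0, 0))
    draw = ImageDraw.Draw(overlay)
    for e, p1, p2, ctrl in edge_paths(net, layout, style):
        rgb = style.type_palette[e.edge_type]
        rgba = rgb + (round(255 * weight_to_alpha(e.weight)),)
        if ctrl is None:
            draw.line([p1, p2], fill=rgba, width=2)
        else:
            samples = [_point_on_path(p1, p2, ctrl, t / 32)[0] for t in range(33)]
            draw.line(samples, fill=rgba, width=2)
        directed = net.directed if e.directed is None else e.directed
        if directed and style.arrowheads:
            draw.polygon(_arrowhead_points(p1, p2, ctrl), fill=rgba)
    img = Image.alpha_composite(img.convert("RGBA"), overlay).convert("RGB")

    draw = ImageDraw.Draw(img)
    r = style.node_radius
    for node in net.nodes:
        x, y = layout.coords[node.name]
        cx, cy = x * W, y * H
        color = node.color
        if clustering is not None and node.name in clustering.assignment:
            color = clustering.colors[clustering.assignment[node.name]]
        outline = (51, 51, 51)
        if node.shape == "circle":
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=color, outline=outline)
        elif node.shape == "rectangle":
            draw.rectangle([cx - r, cy - r, cx + r, cy + r], fill=color, outline=outline)
        else:
            draw.polygon(_shape_points(node.shape, cx, cy, r), fill=color, outline=outline)
        if style.show_labels:
            draw.text((cx + r + 3, cy - 5), node.name, fill=(0, 0, 0))
    img.save(path, format="PNG")


# ---------------------------------------------------------------------------
# view transform


def apply_view_transform(
    layout: LayoutResult,
    zoom: float = 1.0,
    rotation: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
) -> LayoutResult:
    """Rotate about (0.5, 0.5), scale about (0.5, 0.5), then translate.

    Output coordinates are clamped back into the unit square; the names of
    clamped nodes are reported in ``result.params['clamped_nodes']``.
    """
    if zoom <= 0:
        raise ValueError(f"zoom must be > 0, got {zoom!r}")
    cos_t, sin_t = math.cos(rotation), math.sin(rotation)
    dx, dy = translation
    coords = {}
    clamped = []
    for name, (x, y) in layout.coords.items():
        rx, ry = x - 0.5, y - 0.5
        qx = cos_t * rx - sin_t * ry
        qy = sin_t * rx + cos_t * ry
        nx = 0.5 + zoom * qx + dx
        ny = 0.5 + zoom * qy + dy
        if not (0.0 <= nx <= 1.0 and 0.0 <= ny <= 1.0):
            clamped.append(name)
            nx = min(max(nx, 0.0), 1.0)
            ny = min(max(ny, 0.0), 1.0)
        coords[name] = (nx, ny)
    params = dict(layout.params)
    params["clamped_nodes"] = sorted(clamped)
    return LayoutResult(coords=coords, algorithm=layout.algorithm, seed=layout.seed, params=params)
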