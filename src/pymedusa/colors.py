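"""Fixed color palettes.

``EDGE_TYPE_PALETTE`` maps the eight edge types to eight visually distinct
colors; the mapping is part of the rendering contract (every evidence
channel keeps its color across drawings).  ``CLUSTER_PALETTE`` is the
12-color cluster palette; beyond 12 clusters it is cycled with a shade
shift so ids still get distinguishable colors.
"""

from __future__ import annotations

EDGE_TYPE_PALETTE: dict[int, tuple[int, int, int]] = {
    1: (31, 119, 180),   # blue
    2: (214, 39, 40),    # red
    3: (44, 160, 44),    # green
    4: (255, 127, 14),   # orange
    5: (148, 103, 189),  # purple
    6: (140, 86, 75),    # brown
    7: (227, 119, 194),  # pink
    8: (23, 190, 207),   # cyan
}

CLUSTER_PALETTE: tuple[tuple[int, int, int], ...] = (
    (141, 211, 199),
    (255, 255, 179),
    (190, 186, 218),
    (251, 128, 114),
    (128, 177, 211),
    (253, 180, 98),
    (179, 222, 105),
    (252, 205, 229),
    (217, 217, 217),
    (188, 128, 189),
    (204, 235, 197),
    (255, 237, 111),
)


def cluster_color(cluster_id: int) -> tuple[int, int, int]:
    """Color for a cluster id; cycles the palette darkening each wrap."""
    base = CLUSTER_PALETTE[cluster_id % len(CLUSTER_PALETTE)]
    wraps = cluster_id // len(CLUSTER_PALETTE)
    factor = 0.65 ** wraps
    return tuple(max(0, min(255, round(c * factor))) for c in base)


def to_hex(color: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*color)


def parse_color(text: str) -> tuple[int, int, int]:
    """Parse ``R,G,B`` or ``#RRGGBB`` color syntax."""
    text = text.strip()
    if text.startswith("#"):
        if len(text) != 7:
            raise ValueError(f"hex color must be #RRGGBB, got {text!r}")
        return tuple(int(text[i : i + 2], 16) for i in (1, 3, 5))
    parts = text.split(",")
    if len(parts) != 3:
        raise ValueError(f"color must be R,G,B or #RRGGBB, got {text!r}")
    return tuple(int(p) for p in parts)
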