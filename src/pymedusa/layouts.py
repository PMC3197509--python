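"""Node placement algorithms.

All layouts place every node of the network at coordinates inside the unit
square (screen convention, origin top-left) with a 5% margin, and are
deterministic given their seed and parameters:

* ``grid`` / ``random`` / ``circular`` — simple distributions;
* ``force_directed`` — Fruchterman–Reingold force simulation;
* ``spring`` — Kamada–Kawai stress minimisation over graph distances;
* ``distance_geometry`` — classical metric multidimensional scaling of a
  weighted shortest-path dissimilarity, so strongly connected (highly
  weighted) nodes land close together;
* ``hierarchical`` — BFS layering from roots, barycenter x-ordering;
* ``parallel_axes`` — one vertical axis per node group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import scipy.optimize
import scipy.sparse
import scipy.sparse.csgraph

from .core import Network

MARGIN = 0.05


@dataclass
class LayoutParams:
    """Free parameters of the iterative layouts.

    ``ideal_length_constant`` scales the Fruchterman–Reingold spring length
    ``k = C * sqrt(area / n)`` (unit-square area).  Cooling is a linear
    temperature ramp from ``initial_temperature`` down to zero.
    """

    iterations: int = 100
    ideal_length_constant: float = 1.0
    initial_temperature: float = 0.1
    mds_metric: str = "one_minus_weight_path"  # or "shortest_path"
    mds_epsilon: float = 0.01

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.ideal_length_constant <= 0:
            raise ValueError("ideal_length_constant must be > 0")
        if self.mds_metric not in ("shortest_path", "one_minus_weight_path"):
            raise ValueError(f"unknown mds_metric {self.mds_metric!r}")


@dataclass
class LayoutResult:
    """Mapping node name -> (x, y) in [0,1]^2, tagged with provenance."""

    coords: dict[str, tuple[float, float]]
    algorithm: str
    seed: Optional[int] = None
    params: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.coords[name]

    def __contains__(self, name: str) -> bool:
        return name in self.coords


# ---------------------------------------------------------------------------
# helpers


def _rescale_unit(pos: np.ndarray, margin: float = MARGIN) -> np.ndarray:
    """Map positions into [margin, 1-margin]^2 with a single uniform scale
    about the bounding-box center, preserving the layout's aspect ratio
    (distance ratios survive the rescale).  Degenerate (single-point)
    input collapses to the center."""
    if len(pos) == 0:
        return np.empty((0, 2))
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    extent = float((hi - lo).max())
    if extent < 1e-12:
        return np.full_like(pos, 0.5, dtype=float)
    scale = (1 - 2 * margin) / extent
    center = (lo + hi) / 2
    return 0.5 + (pos - center) * scale


def _result(names, pos, algorithm, seed=None, params=None) -> LayoutResult:
    coords = {n: (float(x), float(y)) for n, (x, y) in zip(names, pos)}
    return LayoutResult(coords=coords, algorithm=algorithm, seed=seed, params=params or {})


def _pair_weights(net: Network) -> dict[tuple[str, str], float]:
    """Max edge weight per unordered connected pair (strongest evidence)."""
    pairs: dict[tuple[str, str], float] = {}
    for e in net.edges:
        p = e.pair()
        pairs[p] = max(pairs.get(p, 0.0), e.weight)
    return pairs


def _adjacency(net: Network, weighted: bool = True) -> np.ndarray:
    """Symmetric (max-weight) adjacency matrix in lexicographic node order."""
    names = net.node_names
    index = {n: i for i, n in enumerate(names)}
    A = np.zeros((len(names), len(names)))
    for (a, b), w in _pair_weights(net).items():
        A[index[a], index[b]] = A[index[b], index[a]] = w if weighted else 1.0
    return A


def _components(net: Network) -> list[list[str]]:
    from .core import connected_components

    return [sorted(c) for c in connected_components(net)]


# ---------------------------------------------------------------------------
# simple layouts


def layout_grid(net: Network) -> LayoutResult:
    """Row-major grid of ceil(sqrt(n)) columns, lexicographic node order."""
    names = net.node_names
    n = len(names)
    if n == 0:
        return _result([], np.empty((0, 2)), "grid")
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    pos = []
    for i in range(n):
        r, c = divmod(i, cols)
        x = 0.5 if cols == 1 else MARGIN + (1 - 2 * MARGIN) * c / (cols - 1)
        y = 0.5 if rows == 1 else MARGIN + (1 - 2 * MARGIN) * r / (rows - 1)
        pos.append((x, y))
    return _result(names, np.array(pos), "grid")


def layout_random(net: Network, seed: int = 0) -> LayoutResult:
    """Uniform positions in [0.05, 0.95]^2, reproducible by seed."""
    names = net.node_names
    rng = np.random.default_rng(seed)
    pos = rng.uniform(MARGIN, 1 - MARGIN, size=(len(names), 2))
    return _result(names, pos, "random", seed=seed)


def layout_circular(net: Network) -> LayoutResult:
    """Equally spaced on a radius-0.45 circle, starting at 12 o'clock."""
    names = net.node_names
    n = len(names)
    pos = []
    for i in range(n):
        theta = -math.pi / 2 + 2 * math.pi * i / n
        pos.append((0.5 + 0.45 * math.cos(theta), 0.5 + 0.45 * math.sin(theta)))
    return _result(names, np.array(pos).reshape(n, 2), "circular")


# ---------------------------------------------------------------------------
# Fruchterman–Reingold


def fr_positions(
    net: Network, params: Optional[LayoutParams] = None, seed: int = 0
) -> tuple[list[str], np.ndarray, float]:
    """Raw Fruchterman–Reingold simulation (before unit-square rescaling).

    Returns (names, positions, k) where k is the ideal spring length.
    Repulsion k^2/d acts between all pairs, attraction d^2/k along each
    connected pair; per-iteration displacement is capped by a linearly
    cooling temperature.
    """
    params = params or LayoutParams()
    names = net.node_names
    n = len(names)
    k = params.ideal_length_constant * math.sqrt(1.0 / max(n, 1))
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 1, size=(n, 2))
    if n <= 1:
        return names, np.full((n, 2), 0.5), k

    A = _adjacency(net, weighted=False) > 0
    iters = params.iterations
    for it in range(iters):
        t = params.initial_temperature * (1 - it / iters)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(dist, np.inf)
        # nudge coincident nodes apart deterministically
        zero = dist < 1e-9
        if zero.any():
            dist[zero] = 1e-9
        unit = diff / dist[:, :, None]
        force = k * k / dist  # repulsion, all pairs
        force = force - np.where(A, dist**2 / k, 0.0)  # attraction on edges
        disp = (unit * force[:, :, None]).sum(axis=1)
        length = np.sqrt((disp**2).sum(axis=1))
        length = np.maximum(length, 1e-12)
        pos = pos + disp / length[:, None] * np.minimum(length, t)[:, None]
    return names, pos, k


def layout_force_directed(
    net: Network, params: Optional[LayoutParams] = None, seed: int = 0
) -> LayoutResult:
    """Fruchterman–Reingold layout rescaled into the unit square."""
    params = params or LayoutParams()
    names, pos, k = fr_positions(net, params, seed)
    if len(names) == 0:
        return _result([], pos, "force_directed", seed=seed)
    pos = _rescale_unit(pos)
    return _result(
        names,
        pos,
        "force_directed",
        seed=seed,
        params={"iterations": params.iterations, "k": k},
    )


# ---------------------------------------------------------------------------
# Kamada–Kawai spring embedding


def _kk_stress(x: np.ndarray, L: np.ndarray, W: np.ndarray):
    P = x.reshape(-1, 2)
    diff = P[:, None, :] - P[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 1.0)
    d = np.maximum(d, 1e-12)
    delta = d - L
    np.fill_diagonal(delta, 0.0)
    stress = 0.5 * float((W * delta**2).sum())
    coeff = W * delta / d
    np.fill_diagonal(coeff, 0.0)
    grad = 2.0 * (coeff[:, :, None] * diff).sum(axis=1)
    return stress, grad.ravel()


def _kk_component(names: list[str], net: Network) -> np.ndarray:
    n = len(names)
    if n == 1:
        return np.array([[0.5, 0.5]])
    index = {m: i for i, m in enumerate(names)}
    A = np.zeros((n, n))
    for (a, b), _w in _pair_weights(net).items():
        if a in index and b in index:
            A[index[a], index[b]] = A[index[b], index[a]] = 1.0
    D = scipy.sparse.csgraph.shortest_path(scipy.sparse.csr_matrix(A), unweighted=True)
    L = D / D.max()
    W = 1.0 / np.maximum(L, 1e-12) ** 2
    np.fill_diagonal(W, 0.0)
    # deterministic circular initialisation
    theta = -math.pi / 2 + 2 * math.pi * np.arange(n) / n
    x0 = np.column_stack([0.5 * np.cos(theta), 0.5 * np.sin(theta)]).ravel()
    res = scipy.optimize.minimize(
        _kk_stress,
        x0,
        args=(L, W),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.x.reshape(n, 2)


def layout_spring(net: Network, params: Optional[LayoutParams] = None) -> LayoutResult:
    """Kamada–Kawai stress minimisation over all-pairs shortest-path
    distances; disconnected components are laid out independently and
    packed left-to-right.  Deterministic (circular initialisation)."""
    names = net.node_names
    if not names:
        return _result([], np.empty((0, 2)), "spring")
    comps = _components(net)
    m = len(comps)
    coords: dict[str, tuple[float, float]] = {}
    for i, comp in enumerate(comps):
        pos = _rescale_unit(_kk_component(comp, net))
        for name, (x, y) in zip(comp, pos):
            coords[name] = ((i + x) / m, float(y))
    return LayoutResult(coords=coords, algorithm="spring", params={"components": m})


# ---------------------------------------------------------------------------
# distance geometry (classical MDS)


def classical_mds(D: np.ndarray, ndim: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared dissimilarity matrix and embeds on the top
    ``ndim`` eigenpairs; exact for Euclidean input.  Eigenvector signs are
    fixed (largest-magnitude entry positive) for determinism.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:ndim]
    coords = np.zeros((n, ndim))
    for j, idx in enumerate(order):
        lam = max(vals[idx], 0.0)
        v = vecs[:, idx]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, j] = v * math.sqrt(lam)
    return coords


def graph_dissimilarity(net: Network, params: Optional[LayoutParams] = None) -> tuple[list[str], np.ndarray]:
    """Weighted shortest-path dissimilarity matrix in lexicographic order.

    Edge length is ``(1 - weight) + epsilon`` (default metric), so highly
    weighted pairs are near; with ``mds_metric='shortest_path'`` plain hop
    counts are used.  Disconnected pairs get 1.2x the largest finite
    distance.
    """
    params = params or LayoutParams()
    names = net.node_names
    n = len(names)
    index = {m: i for i, m in enumerate(names)}
    graph = np.zeros((n, n))
    for (a, b), w in _pair_weights(net).items():
        length = 1.0 if params.mds_metric == "shortest_path" else (1.0 - w) + params.mds_epsilon
        graph[index[a], index[b]] = graph[index[b], index[a]] = length
    D = scipy.sparse.csgraph.shortest_path(scipy.sparse.csr_matrix(graph), method="D")
    finite = D[np.isfinite(D)]
    fill = 1.2 * finite.max() if finite.size and finite.max() > 0 else 1.0
    D[~np.isfinite(D)] = fill
    np.fill_diagonal(D, 0.0)
    return names, D


def layout_distance_geometry(
    net: Network, params: Optional[LayoutParams] = None
) -> LayoutResult:
    """Classical-MDS embedding of the graph dissimilarity: the stronger two
    nodes are connected, the closer they are placed."""
    params = params or LayoutParams()
    names = net.node_names
    n = len(names)
    if n == 0:
        return _result([], np.empty((0, 2)), "distance_geometry")
    if n == 1:
        return _result(names, np.array([[0.5, 0.5]]), "distance_geometry")
    names, D = graph_dissimilarity(net, params)
    pos = _rescale_unit(classical_mds(D))
    return _result(names, pos, "distance_geometry", params={"metric": params.mds_metric})


# ---------------------------------------------------------------------------
# hierarchical


def layout_hierarchical(net: Network) -> LayoutResult:
    """Tree-like layering: roots on top, BFS depth sets y, within-layer x
    ordered by the barycenter of parent positions.

    Roots are in-degree-0 nodes for directed networks (falling back to the
    lexicographically smallest node of a rootless cyclic component) and one
    minimum-eccentricity node per component for undirected networks.
    """
    names = net.node_names
    n = len(names)
    if n == 0:
        return _result([], np.empty((0, 2)), "hierarchical")

    succ: dict[str, set[str]] = {m: set() for m in names}
    pred: dict[str, set[str]] = {m: set() for m in names}
    for e in net.edges:
        succ[e.source].add(e.target)
        pred[e.target].add(e.source)
        if not net.directed:
            succ[e.target].add(e.source)
            pred[e.source].add(e.target)

    comps = _components(net)
    roots: list[str] = []
    for comp in comps:
        if net.directed:
            comp_roots = [m for m in comp if not pred[m]]
            roots.extend(comp_roots if comp_roots else [min(comp)])
        else:
            roots.append(_min_eccentricity_node(comp, succ))

    depth: dict[str, int] = {}
    queue = sorted(roots)
    for r in queue:
        depth[r] = 0
    while True:
        while queue:
            u = queue.pop(0)
            for v in sorted(succ[u]):
                if v not in depth:
                    depth[v] = depth[u] + 1
                    queue.append(v)
        unreached = [m for m in names if m not in depth]
        if not unreached:
            break
        extra = min(unreached)  # e.g. a directed cycle fed only by itself
        depth[extra] = 0
        queue = [extra]

    max_depth = max(depth.values())
    layers: dict[int, list[str]] = {}
    for m in names:
        layers.setdefault(depth[m], []).append(m)

    coords: dict[str, tuple[float, float]] = {}
    for d in range(max_depth + 1):
        layer = layers.get(d, [])
        if d == 0:
            layer.sort()
        else:
            def barycenter(m: str) -> float:
                parents = [p for p in (pred[m] | succ[m]) if depth.get(p, 99) == d - 1]
                if not parents:
                    return 0.5
                return sum(coords[p][0] for p in parents) / len(parents)

            layer.sort(key=lambda m: (barycenter(m), m))
        y = 0.5 if max_depth == 0 else MARGIN + (1 - 2 * MARGIN) * d / max_depth
        for i, m in enumerate(layer):
            x = MARGIN + (1 - 2 * MARGIN) * (i + 0.5) / len(layer)
            coords[m] = (x, y)
    return LayoutResult(coords=coords, algorithm="hierarchical")


def _min_eccentricity_node(comp: list[str], adj: Mapping[str, set[str]]) -> str:
    best, best_ecc = None, None
    for start in sorted(comp):
        seen = {start: 0}
        queue = [start]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if v in comp and v not in seen:
                    seen[v] = seen[u] + 1
                    queue.append(v)
        ecc = max(seen.values())
        if best_ecc is None or ecc < best_ecc:
            best, best_ecc = start, ecc
    return best


# ---------------------------------------------------------------------------
# parallel axes


def layout_parallel_axes(net: Network, groups) -> LayoutResult:
    """One vertical axis per node group (Arena3D-style layers flattened to
    parallel coordinate axes).

    *groups* is a mapping node name -> group label, or a ``Clustering``
    (cluster ids become the groups).  Nodes missing a group go to a
    trailing ``unassigned`` axis.
    """
    if hasattr(groups, "assignment"):
        mapping = {name: f"cluster{cid}" for name, cid in groups.assignment.items()}
    else:
        mapping = dict(groups)
    names = net.node_names
    if not names:
        return _result([], np.empty((0, 2)), "parallel_axes")
    labelled = sorted({mapping[m] for m in names if m in mapping})
    has_unassigned = any(m not in mapping for m in names)
    axes = labelled + (["unassigned"] if has_unassigned else [])
    k = len(axes)
    members: dict[str, list[str]] = {a: [] for a in axes}
    for m in names:
        members[mapping.get(m, "unassigned")].append(m)
    coords: dict[str, tuple[float, float]] = {}
    for i, axis in enumerate(axes):
        x = (i + 0.5) / k
        col = sorted(members[axis])
        for j, m in enumerate(col):
            y = 0.5 if len(col) == 1 else MARGIN + (1 - 2 * MARGIN) * j / (len(col) - 1)
            coords[m] = (x, y)
    return LayoutResult(coords=coords, algorithm="parallel_axes", params={"axes": axes})
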