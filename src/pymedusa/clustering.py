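"""Embedded clustering of network nodes.

Three algorithms operate directly on the graph:

* **k-means** — Lloyd iterations with k-means++ seeding, best of 10
  restarts, on either the rows of the symmetric weighted adjacency matrix
  (graph-intrinsic, the default) or on layout coordinates;
* **spectral** — normalized symmetric Laplacian ``I - D^{-1/2} W D^{-1/2}``
  with edge weights as affinities, embedding on the k bottom eigenvectors
  (rows renormalised to unit length), then k-means on the embedding;
* **affinity propagation** — exemplar-based message passing on a
  similarity matrix built from edge weights (non-edges floored at -1),
  with damping and a stable-exemplar convergence window.

Pre-computed partitions can be read from / written to a two-column
tab-separated text file, and any partition can be drawn with one circle
per cluster and a unique color per cluster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from .colors import cluster_color
from .core import Network
from .errors import ParseError, UnknownNodeError
from .layouts import LayoutResult, _adjacency


@dataclass
class Clustering:
    """A partition of the network's nodes.

    Cluster ids are contiguous integers ``0..k-1``; every cluster id gets a
    color from the fixed 12-color palette (cycled with a shade shift when
    k exceeds the palette).  ``exemplars`` maps cluster id to the exemplar
    node for affinity propagation.
    """

    assignment: dict[str, int]
    k: int
    colors: dict[int, tuple[int, int, int]]
    method: str
    exemplars: Optional[dict[int, str]] = None
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def members(self, cluster_id: int) -> list[str]:
        return sorted(n for n, c in self.assignment.items() if c == cluster_id)


def _finish(assignment: dict[str, int], method: str, exemplars=None, converged=True, meta=None) -> Clustering:
    k = (max(assignment.values()) + 1) if assignment else 0
    return Clustering(
        assignment=assignment,
        k=k,
        colors={c: cluster_color(c) for c in range(k)},
        method=method,
        exemplars=exemplars,
        converged=converged,
        meta=meta or {},
    )


def _relabel_first_appearance(names: list[str], labels: np.ndarray) -> dict[str, int]:
    """Relabel raw cluster labels to contiguous ids in order of first
    appearance over the (lexicographically sorted) node list."""
    mapping: dict[int, int] = {}
    out = {}
    for name, lab in zip(names, labels):
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[name] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# k-means


def kmeans_features(
    X: np.ndarray, k: int, seed: int = 0, restarts: int = 10, max_iter: int = 300
) -> tuple[np.ndarray, float, list[float]]:
    """Lloyd's algorithm with k-means++ seeding, best of *restarts* runs
    (seeds ``seed..seed+restarts-1``).

    Returns (labels, objective, objective_history_of_best_run).  The
    within-cluster sum of squares is non-increasing across iterations;
    nearest-centroid ties break toward the lowest cluster id.
    """
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    best = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        centers = _kmeanspp(X, k, rng)
        history: list[float] = []
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels = np.argmin(d2, axis=1)  # argmin -> lowest id on ties
            obj = float(d2[np.arange(n), labels].sum())
            history.append(obj)
            new_centers = centers.copy()
            for c in range(k):
                mask = labels == c
                if mask.any():
                    new_centers[c] = X[mask].mean(axis=0)
                else:  # re-seed an empty cluster at the worst-fit point
                    far = int(np.argmax(d2[np.arange(n), labels]))
                    new_centers[c] = X[far]
            if np.allclose(new_centers, centers, rtol=0, atol=1e-12):
                break
            centers = new_centers
        if best is None or history[-1] < best[1] - 1e-12:
            best = (labels, history[-1], history)
    return best


def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [X[int(rng.integers(n))]]
    for _ in range(1, k):
        d2 = np.min(((X[:, None, :] - np.array(centers)[None, :, :]) ** 2).sum(axis=2), axis=1)
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers.append(X[idx])
    return np.array(centers, dtype=float)


def cluster_kmeans(
    net: Network,
    k: int,
    seed: int = 0,
    feature_source: str = "adjacency_rows",
    layout: Optional[LayoutResult] = None,
) -> Clustering:
    """k-means partition of the nodes.

    ``feature_source='adjacency_rows'`` clusters rows of the symmetric
    weighted adjacency matrix; ``'coordinates'`` clusters layout positions
    (requires *layout*).
    """
    names = net.node_names
    if feature_source == "adjacency_rows":
        X = _adjacency(net, weighted=True)
    elif feature_source == "coordinates":
        if layout is None:
            raise ValueError("feature_source='coordinates' requires a layout")
        X = np.array([layout.coords[n] for n in names], dtype=float)
    else:
        raise ValueError(f"unknown feature_source {feature_source!r}")
    labels, obj, history = kmeans_features(X, k, seed=seed)
    assignment = _relabel_first_appearance(names, labels)
    return _finish(assignment, "kmeans", meta={"objective": obj, "objective_history": history})


# ---------------------------------------------------------------------------
# spectral


def cluster_spectral(net: Network, k: int, seed: int = 0) -> Clustering:
    """Normalized-cut style spectral clustering with weights as affinities."""
    names = net.node_names
    n = len(names)
    if not (2 <= k <= n):
        raise ValueError(f"k must satisfy 2 <= k <= {n}, got {k}")
    W = _adjacency(net, weighted=True)
    deg = W.sum(axis=1)
    deg = np.maximum(deg, 1e-12)  # isolated nodes
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - d_inv_sqrt[:, None] * W * d_inv_sqrt[None, :]
    L = (L + L.T) / 2
    vals, vecs = scipy.linalg.eigh(L)
    U = vecs[:, np.argsort(vals)[:k]]
    norms = np.sqrt((U**2).sum(axis=1))
    U = U / np.maximum(norms, 1e-12)[:, None]
    labels, obj, history = kmeans_features(U, k, seed=seed)
    assignment = _relabel_first_appearance(names, labels)
    return _finish(assignment, "spectral", meta={"objective": obj, "objective_history": history})


# ---------------------------------------------------------------------------
# affinity propagation


@dataclass
class APParams:
    """Affinity-propagation controls: damping in [0.5, 1), an iteration
    cap, a window of iterations with a stable exemplar set that counts as
    convergence, and the self-similarity ("preference"; the median of
    off-diagonal similarities by default — more negative gives fewer
    clusters)."""

    damping: float = 0.5
    max_iterations: int = 200
    convergence_window: int = 50
    preference: float | str = "median"

    def __post_init__(self):
        if not (0.5 <= self.damping < 1.0):
            raise ValueError("damping must lie in [0.5, 1)")


def similarity_matrix(net: Network) -> tuple[list[str], np.ndarray]:
    """Pairwise similarity: max edge weight where an edge exists, -1 for
    non-edges (below any weight); the diagonal is left at 0 for the caller
    to fill with the preference."""
    names = net.node_names
    S = _adjacency(net, weighted=True)
    mask = S == 0
    np.fill_diagonal(mask, False)
    S[mask] = -1.0
    return names, S


def ap_cluster(
    S: np.ndarray, params: Optional[APParams] = None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Affinity propagation on a pre-built similarity matrix.

    The diagonal of *S* is overwritten with the preference.  Returns
    (exemplar_indices, labels, converged): standard responsibility /
    availability message passing with damping; exemplars are the points
    with positive self responsibility+availability, and every point joins
    the exemplar it is most similar to.
    """
    params = params or APParams()
    S = np.array(S, dtype=float)
    n = S.shape[0]
    if n == 1:
        return np.array([0]), np.array([0]), True
    if params.preference == "median":
        off = S[~np.eye(n, dtype=bool)]
        pref = float(np.median(off))
    else:
        pref = float(params.preference)
    np.fill_diagonal(S, pref)
    # break exact symmetry ties (degenerate for plain message passing) with
    # a deterministic, vanishingly small jitter
    rng = np.random.default_rng(0)
    S = S + (np.finfo(float).eps * S + np.finfo(float).tiny * 100) * rng.standard_normal(S.shape)

    lam = params.damping
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    prev_exemplars: Optional[frozenset] = None
    stable = 0
    converged = False
    for _ in range(params.max_iterations):
        # responsibilities
        AS = A + S
        idx_max = np.argmax(AS, axis=1)
        first_max = AS[np.arange(n), idx_max]
        AS_tmp = AS.copy()
        AS_tmp[np.arange(n), idx_max] = -np.inf
        second_max = AS_tmp.max(axis=1)
        max_other = np.full((n, n), first_max[:, None])
        max_other[np.arange(n), idx_max] = second_max
        R = lam * R + (1 - lam) * (S - max_other)
        # availabilities
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, R.diagonal())
        col_sums = Rp.sum(axis=0)
        A_new = col_sums[None, :] - Rp
        dA = A_new.diagonal().copy()
        A_new = np.minimum(A_new, 0)
        np.fill_diagonal(A_new, dA)
        A = lam * A + (1 - lam) * A_new

        exemplars = frozenset(np.flatnonzero(np.diag(A) + np.diag(R) > 0).tolist())
        if exemplars and exemplars == prev_exemplars:
            stable += 1
            if stable >= params.convergence_window:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    diag = np.diag(A) + np.diag(R)
    exemplar_idx = np.flatnonzero(diag > 0)
    if exemplar_idx.size == 0:
        exemplar_idx = np.array([int(np.argmax(diag))])
    # standard final refinement: within each cluster, re-choose the member
    # maximizing the within-cluster similarity sum
    c = np.argmax(S[:, exemplar_idx], axis=1)
    c[exemplar_idx] = np.arange(exemplar_idx.size)
    for k in range(exemplar_idx.size):
        members = np.flatnonzero(c == k)
        if members.size:
            j = int(np.argmax(S[np.ix_(members, members)].sum(axis=0)))
            exemplar_idx[k] = members[j]
    exemplar_idx = np.unique(exemplar_idx)
    labels = exemplar_idx[np.argmax(S[:, exemplar_idx], axis=1)]
    labels[exemplar_idx] = exemplar_idx  # exemplars represent themselves
    # contiguous ids in exemplar index order
    remap = {int(e): i for i, e in enumerate(exemplar_idx)}
    return exemplar_idx, np.array([remap[int(l)] for l in labels]), converged


def cluster_affinity_propagation(net: Network, params: Optional[APParams] = None) -> Clustering:
    """Affinity propagation on the network's edge-weight similarities."""
    params = params or APParams()
    names, S = similarity_matrix(net)
    exemplar_idx, labels, converged = ap_cluster(S, params)
    if not converged:
        warnings.warn("affinity propagation did not converge; returning current exemplars")
    assignment = {name: int(lab) for name, lab in zip(names, labels)}
    exemplars = {i: names[int(e)] for i, e in enumerate(exemplar_idx)}
    k = len(exemplar_idx)
    return Clustering(
        assignment=assignment,
        k=k,
        colors={c: cluster_color(c) for c in range(k)},
        method="affinity_propagation",
        exemplars=exemplars,
        converged=converged,
    )


def net_similarity(S: np.ndarray, exemplar_idx: np.ndarray, preference: float) -> float:
    """Net similarity of an exemplar set: each point contributes its best
    exemplar similarity, each exemplar its preference."""
    S = np.array(S, dtype=float)
    exemplar_set = set(int(e) for e in exemplar_idx)
    total = len(exemplar_set) * preference
    for i in range(S.shape[0]):
        if i not in exemplar_set:
            total += float(S[i, exemplar_idx].max())
    return total


# ---------------------------------------------------------------------------
# predefined clusters, text export, circle layout


def read_predefined_clusters(net: Network, path) -> Clustering:
    """Read ``node<TAB>label`` lines; labels become contiguous ids in
    first-appearance order; nodes absent from the file form one trailing
    ``unclustered`` cluster; rows naming unknown nodes are warned and
    skipped."""
    raw: dict[str, str] = {}
    label_order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(f"expected 'node<TAB>label', got {line!r}", line=lineno)
            name, label = parts[0].strip(), parts[1].strip()
            if not net.has_node(name):
                warnings.warn(f"cluster file line {lineno}: unknown node {name!r} skipped")
                continue
            raw[name] = label
            if label not in label_order:
                label_order.append(label)
    ids = {label: i for i, label in enumerate(label_order)}
    assignment = {}
    leftover = [n for n in net.node_names if n not in raw]
    for name, label in raw.items():
        assignment[name] = ids[label]
    if leftover:
        unclustered_id = len(label_order)
        for name in leftover:
            assignment[name] = unclustered_id
    return _finish(assignment, "predefined")


def export_clusters(clustering: Clustering, path) -> None:
    """Write ``node<TAB>clusterId`` lines, nodes in lexicographic order."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(clustering.assignment):
            fh.write(f"{name}\t{clustering.assignment[name]}\n")


def cluster_circle_layout(net: Network, clustering: Clustering) -> LayoutResult:
    """Place each cluster on its own circle: cluster centers equally spaced
    on a meta-circle (radius 0.35 around the canvas center), members
    equally spaced on their cluster circle (radius ``min(0.12,
    0.3/sqrt(k))``).  A single cluster sits at the center."""
    k = clustering.k
    coords: dict[str, tuple[float, float]] = {}
    if k == 0:
        return LayoutResult(coords={}, algorithm="cluster_circles")
    r_cluster = min(0.12, 0.3 / math.sqrt(k))
    for cid in range(k):
        if k == 1:
            cx, cy = 0.5, 0.5
        else:
            theta = -math.pi / 2 + 2 * math.pi * cid / k
            cx = 0.5 + 0.35 * math.cos(theta)
            cy = 0.5 + 0.35 * math.sin(theta)
        members = clustering.members(cid)
        for j, name in enumerate(members):
            phi = -math.pi / 2 + 2 * math.pi * j / len(members)
            coords[name] = (cx + r_cluster * math.cos(phi), cy + r_cluster * math.sin(phi))
    # nodes the clustering does not cover should never be lost
    for name in net.node_names:
        coords.setdefault(name, (0.5, 0.5))
    return LayoutResult(coords=coords, algorithm="cluster_circles", params={"k": k})
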