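# Methods

This note records the models and procedures pymedusa implements, the
parameters that matter, the numerical choices behind them, and what the
synthetic data used by the test suite does and does not show.

## The multigraph model

A network is a set of uniquely named nodes and a set of edge records
`(source, target, edge_type, weight, orientation)`.  `edge_type` is an
integer in 1..8 encoding the evidence channel (e.g. experimental,
text-mining, co-expression); weights are confidences in [0, 1].  Two
structural rules are enforced at every mutation:

* edge identity is `(source, target, edge_type)`, with the endpoint pair
  order-normalised lexicographically in undirected networks, so A–B and
  B–A name the same record and round trips are deterministic;
* an unordered node pair carries at most 8 edge records.  In directed
  networks both directions of the same type are representable, but the
  8-record budget is shared by the pair — the strictest reading
  consistent with the per-type uniqueness rule.

Self-loops are rejected; degree counts incident edge records under the
undirected interpretation, so Σ deg = 2·|E| always holds.  Density is
the fraction of connected unordered pairs, 0 for n < 2.  Node
coordinates, when present, are normalised to [0, 1]² in screen
convention (origin top-left, y downward) so files are
resolution-independent.

**Collapse/expand.**  Collapsing a group replaces it by one meta-node;
each (outside neighbour, edge type) connection — per direction in
directed networks — becomes a single edge whose weight is the **maximum**
over the merged parallel edges.  Max was chosen over sum or mean because
it preserves the strongest evidence and keeps weights inside [0, 1].
The removed members and every edge touching them are stored on the
network, so expansion restores the original structure exactly; the
round-trip identity is property-tested on 200 random multigraphs.
Deletion of a node, by contrast, is permanent.

**Search** uses substring regular-expression semantics (`re.search`),
matching what interactive search boxes do; full-match behaviour is
available by anchoring the pattern.

## File format

The flat-file dialect and session sidecar are normatively defined in
[FORMAT.md](../FORMAT.md).  Two decisions deserve a note.  Session state
(layout, clustering, background image) lives in a sidecar rather than in
the graph file so the graph file stays readable by anything that speaks
the basic dialect.  And the writer is canonical — sorted entities, fixed
attribute order, shortest round-trip float formatting — which makes
`write ∘ read` idempotent and lets tests compare files byte for byte.
Unknown `key:value` attributes are carried through verbatim rather than
dropped, so third-party extensions survive editing.

## Layouts

All layouts place every node inside the unit square with a 5% margin and
are deterministic given their seed and parameters.  Layouts that compute
geometry (force-directed, spring, distance geometry) are rescaled into
the square with a single uniform scale factor about the bounding-box
center: per-axis rescaling would distort distance ratios (an equilateral
triangle would stop being equilateral), and the contracts below are
stated in terms of distances.

* **Grid / random / circular.**  Row-major grid of ⌈√n⌉ columns in
  lexicographic order; uniform positions in [0.05, 0.95]²; equal spacing
  on a radius-0.45 circle starting at 12 o'clock.
* **Force-directed (Fruchterman–Reingold).**  Repulsion k²/d between all
  pairs, attraction d²/k along each connected pair, displacement capped
  by a temperature cooling linearly from 0.1 (in unit-square units) to 0
  over 100 iterations; k = C·√(area/n) with C = 1 and unit area.  For an
  isolated edge the force balance has the closed-form equilibrium
  d\* = k, which the tests verify to within 10% before rescaling.
  Multi-edges attract once per connected pair (classic FR is unweighted);
  forces are accumulated from a sorted adjacency matrix so the result is
  invariant to edge insertion order.
* **Spring embedding (Kamada–Kawai).**  Stress
  Σ w_ij (‖x_i − x_j‖ − L_ij)² with L the hop-count shortest-path matrix
  scaled to max 1 and w = 1/L², minimised by L-BFGS-B with an analytic
  gradient from a deterministic circular initialisation.  Disconnected
  components are embedded independently and packed left-to-right in
  equal-width slots.
* **Distance geometry (classical MDS).**  Edge length (1 − w) + ε with
  ε = 0.01 (so a weight-1 edge still has positive length and the metric
  is well-defined), Dijkstra shortest paths, disconnected pairs set to
  1.2× the largest finite distance; the dissimilarity matrix is
  double-centered and embedded on the top-2 eigenpairs, with eigenvector
  signs fixed for determinism.  Classical MDS is exact for Euclidean
  input, which gives the standing oracle test: random planar point sets
  fed back as distance matrices are recovered to Procrustes RMS < 1e-6.
  A hop-count metric is available for unweighted graphs.
* **Hierarchical.**  Roots are in-degree-0 nodes (directed) or one
  minimum-eccentricity node per component (undirected); a component that
  is a rootless directed cycle falls back to its lexicographically
  smallest node, and any nodes unreachable along edge directions seed
  additional roots the same way.  BFS depth sets y (single layer
  centered at 0.5); within a layer, x is ordered by the barycenter of
  parent positions with name tie-breaks, which keeps trees planar.
* **Parallel axes.**  One vertical axis per group at x = (i + 0.5)/k in
  group-name order, members evenly spaced top-to-bottom; nodes without a
  group go to a trailing "unassigned" axis.  Groups can be given as a
  plain mapping or a clustering.

## Clustering

* **k-means.**  Lloyd iterations with k-means++ seeding, best of 10
  restarts (seeds s..s+9); nearest-centroid ties break to the lowest
  cluster id; an emptied cluster is re-seeded at the worst-fit point.
  The within-cluster sum of squares is recorded every iteration and is
  non-increasing by construction — tests assert it.  The default feature
  space is the rows of the symmetric max-weight adjacency matrix
  (graph-intrinsic); layout coordinates are an explicit alternative for
  geometric data.
* **Spectral.**  Normalized symmetric Laplacian
  L = I − D^(−1/2) W D^(−1/2) with edge weights as affinities and
  isolated-node degrees floored at 1e-12; the k smallest-eigenvalue
  eigenvectors, rows renormalised to unit length, clustered by the
  k-means above.  When the graph has exactly k connected components the
  zero eigenspace is spanned by component indicators, rows of the
  embedding are identical within a component and orthogonal across
  components, and recovery is exact — tested as ARI = 1.0 on 50 random
  disconnected fixtures.
* **Affinity propagation.**  Similarity s(i, j) is the maximum edge
  weight where an edge exists and −1 (below any weight) otherwise;
  s(i, i) is the preference, defaulting to the median of off-diagonal
  similarities (the standard self-tuning choice; more negative gives
  fewer clusters).  Standard responsibility/availability message passing
  with damping λ = 0.5, at most 200 iterations, convergence declared
  after 50 iterations with a stable exemplar set; a vanishingly small
  deterministic jitter (machine-epsilon scale) breaks exact symmetry
  ties, and the final exemplars are refined per cluster to the member
  maximising the within-cluster similarity sum, as in the reference
  implementations.  Non-convergence is reported on the result
  (`converged=False`) rather than hidden; structurally interchangeable
  members can keep the exemplar identity oscillating at light damping,
  in which case heavier damping settles it.  On random similarity
  matrices with n ≤ 6 the returned exemplar set's net similarity is
  within 5% of the exhaustive optimum over all 2ⁿ − 1 subsets in ≳99.8%
  of cases; the residual shortfall occurs in non-converged runs and is
  reproduced by independent implementations on the same matrices —
  it is inherent to the approximation, not to this implementation.
* **Partitions as data.**  Imported/exported as two-column TSV; labels
  become contiguous 0-based ids in first-appearance order; uncovered
  nodes form one trailing cluster.  Cluster ids map to a fixed 12-color
  palette, cycled with a 0.65 shade factor per wrap, so distinct
  clusters get distinct colors whenever k ≤ 12.
* k is a required parameter for k-means/spectral; no automatic model
  selection is attempted.

## Rendering

SVG output is a pure function of (network, layout, style, clustering):
element order, attribute order and number formatting (2 decimals in
pixel space) are fixed, so identical inputs give identical bytes — the
determinism tests compare raw text.  Parallel edges between a pair are
ranked by type and drawn as quadratic Beziers whose control points sit
at signed perpendicular offsets of 0.03 × canvas width × rank, symmetric
about the straight chord (an odd count keeps the middle edge straight);
an edge's `orientation` field overrides the bow side.  Edge type selects
one of eight fixed colors; weight maps linearly to stroke opacity
0.15 + 0.85·w, chosen over lightness so faint edges stay legible on any
background image.  Directed edges carry a triangular arrowhead at 80% of
the path.  Cluster colors override node fill when a clustering is
passed.  Node elements carry `data-name`, keeping drawings
machine-inspectable.  PNG rendering draws the same geometry through
Pillow (Beziers sampled at 33 points, edges composited once with their
alpha).  View changes (zoom, rotation about the canvas center,
translation) are pure coordinate transforms; out-of-square nodes are
clamped and their names reported.  Label placement is a fixed offset
with no overlap avoidance.

## Synthetic data

All tests run on generated inputs; the `fixtures` module provides
Erdos–Renyi graphs, planted partitions (with block labels), trees,
cycles, multi-edge graphs (1..8 random types per connected pair, uniform
weights), Gaussian point clouds (with labels and true coordinates;
default σ = 0.03 in unit coordinates, cloud centers 10σ apart, 40
points — well-separated by construction), and uniform planar point
sets.  Each generator is deterministic given its spec and one explicit
RNG stream.  These fixtures exercise the algorithms' contracts, but they
are not realistic interactomes: no scale-free degree structure, no
correlated evidence channels, no hubs.  Passing tests certify the
mechanics (capacity enforcement, round trips, recovery of planted
structure under clean separation), not performance on real PPI data,
where cluster boundaries are far less crisp.

The acceptance script (`scripts/acceptance.py`) re-measures the headline
quantities at moderate problem sizes — 100 round-trip documents, 20 MDS
point sets of 10–50 points, 50 spectral fixtures, 200 collapse/filter
fixtures — sizes chosen to make every run complete in seconds while
keeping each estimate stable across seeds.

## Known limitations

* No interactive canvas: dragging, hover and URL opening are out of
  scope; view changes are programmatic transforms.
* SIF has no weight column, so weights are dropped in that exporter
  (relation tokens `type1`..`type8` carry the channel).
* Interchange is export-only; the medusa dialect is the canonical input.
* Collapsing a directed group can need more than 8 records to the
  meta-node when both directions of many types exist; such a collapse
  fails loudly rather than silently merging directions.
* Hierarchical layout handles cycles by the documented
  smallest-name-root rule; there is no feedback-arc minimisation.
* Affinity propagation on sparse unweighted graphs assigns nodes by
  direct similarity to an exemplar, so nodes without an edge to any
  exemplar sit on ties; spectral or k-means are better suited there.
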