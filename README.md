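# pymedusa

Exploration, layout, clustering and rendering of multi-edged biological
networks, as a Python library with a thin `pymedusa` command line.

Systems-biology data rarely comes as a simple graph: two proteins may
interact in an experiment, co-occur in the literature, co-express in a
compendium and share homology all at once, each with its own confidence.
pymedusa models such data as a weighted multigraph in which one node pair
carries up to **eight typed parallel edges** — one per evidence channel,
each with a confidence weight w ∈ [0, 1] — and gives the people who work
with these networks (interaction-database curators, pathway modellers,
anyone integrating heterogeneous evidence) a scriptable way to load,
edit, analyse, cluster, export and draw them.

## What is inside

* **Graph model** — directed/undirected multigraphs with per-node color,
  shape, coordinates, annotation and URL; editing, weight/type filtering,
  edge isolation, regex search, group collapse/expand (lossless), and
  simple statistics (degrees, components, density).
* **Persistence** — a simple flat text format (normative grammar in
  [FORMAT.md](FORMAT.md)) plus a session sidecar, with a canonical writer:
  `read(write(d)) == d` exactly.
* **Layouts** — grid, random, circular, hierarchical (BFS layering with
  barycenter ordering), Fruchterman–Reingold force simulation
  (repulsion k²/d, attraction d²/k, linear cooling, k = C·√(area/n)),
  Kamada–Kawai stress minimisation over shortest-path distances,
  distance geometry (classical MDS of the weighted shortest-path metric
  with edge length (1 − w) + ε, so strongly supported pairs land close),
  and parallel coordinate axes per node group.
* **Clustering** — k-means (k-means++ seeding, best of 10 restarts, on
  adjacency rows or layout coordinates), spectral clustering on the
  normalized Laplacian L = I − D^(−1/2) W D^(−1/2), affinity propagation
  on edge-weight similarities (non-edges floored at −1), import/export of
  partitions as two-column TSV, a circles-per-cluster layout, and a fixed
  12-color cluster palette.
* **Interchange** — deterministic exporters to Pajek NET, Cytoscape SIF
  and GraphViz DOT.
* **Rendering** — deterministic SVG (byte-identical for identical
  inputs) and PNG: parallel edges fan out as Bezier curves, one fixed
  color per edge type, confidence drawn as line opacity
  (0.15 + 0.85·w), arrowheads on directed edges, optional raster
  background image, focus sets for edge isolation, and pure
  zoom/rotate/translate view transforms.

## A worked example

```python
import pymedusa as pm

net = pm.Network()
for name in ("TP53", "MDM2", "CDKN1A"):
    net.add_node(pm.Node(name=name))
net.add_edge(pm.Edge(source="TP53", target="MDM2", edge_type=1, weight=0.95))
net.add_edge(pm.Edge(source="TP53", target="MDM2", edge_type=2, weight=0.80))
net.add_edge(pm.Edge(source="TP53", target="CDKN1A", edge_type=1, weight=0.90))

s = pm.stats(net)
print(s.n_nodes, s.n_edges, s.n_pairs, s.per_type_counts)

layout = pm.layout_force_directed(net, seed=0)
svg = pm.render_svg(net, layout)
```

The statistics line prints

```
3 3 2 {1: 2, 2: 1}
```

three nodes, three edge records spread over two connected pairs, two of
the records on channel 1 and one on channel 2 — the TP53–MDM2 pair alone
carries two parallel edges, which the renderer draws as mirrored Bezier
curves in the two channel colors.  The `examples/` directory holds five
short scripts, one per capability, each printing the quantities it
computes and what they mean.

The same flows are available from the shell:

```sh
pymedusa stats network.medusa
pymedusa convert network.medusa --to pajek -o network.net
pymedusa layout network.medusa --algo force_directed --seed 0 -o laid.medusa
pymedusa cluster laid.medusa --method spectral -k 3 -o clustered.medusa
pymedusa render clustered.medusa --min-weight 0.4 --format svg -o network.svg
pymedusa search network.medusa --pattern '^TP' --fields name,annotation
```

## Documentation

* [FORMAT.md](FORMAT.md) — the flat-file dialect, session sidecar and
  cluster TSV, with a grammar.
* [docs/methods.md](docs/methods.md) — models, parameters, numerical
  choices, what the synthetic generators do and do not emulate, known
  limitations.
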