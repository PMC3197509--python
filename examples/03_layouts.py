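"""Run every layout algorithm on one network and compare what each
optimizes.  All layouts place nodes in the unit square (origin top-left)
and are reproducible given their seed."""

import math

import pymedusa as pm
from pymedusa.fixtures import FixtureSpec, generate

fx = generate(FixtureSpec(kind="planted_partition",
                          params={"k": 2, "block_size": 6, "p_in": 0.8, "p_out": 0.05},
                          seed=4))
net = fx.network
print(f"network: {net.n_nodes} nodes in two dense blocks, {net.n_edges} edges\n")


def mean_edge_length(layout):
    return sum(
        math.dist(layout.coords[e.source], layout.coords[e.target]) for e in net.edges
    ) / net.n_edges


for name in ("grid", "random", "circular", "force_directed", "spring", "distance_geometry"):
    layout = pm.LAYOUTS[name](net, seed=0)
    print(f"{name:>18}: mean edge length {mean_edge_length(layout):.3f}")
# Structure-aware layouts (force_directed, spring, distance_geometry) pull
# connected nodes together, so their mean edge length is far below the
# structure-blind grid/random/circular baselines.

# Hierarchical layering on a directed tree: depth becomes the y coordinate.
tree = generate(FixtureSpec(kind="tree", params={"depth": 2, "directed": True}))
layout = pm.layout_hierarchical(tree.network)
levels = sorted({round(y, 2) for _, y in layout.coords.values()})
print(f"\nhierarchical tree levels (y per BFS depth): {levels}")

# Parallel axes: one vertical axis per node group.
groups = {name: f"block{label}" for name, label in fx.labels.items()}
axes = pm.layout_parallel_axes(net, groups)
print(f"parallel axes at x = {sorted({round(x, 2) for x, _ in axes.coords.values()})}")
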