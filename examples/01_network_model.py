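"""Build a small heterogeneous interaction network and interrogate it.

Two genes can be linked through several evidence channels at once
(co-expression, text mining, homology, ...); each channel is a separate
typed edge with its own confidence weight.
"""

import pymedusa as pm

net = pm.Network()
for name, ann in [
    ("TP53", "tumor suppressor, DNA damage response"),
    ("MDM2", "E3 ubiquitin ligase, TP53 regulator"),
    ("CDKN1A", "cyclin-dependent kinase inhibitor p21"),
    ("BRCA1", "DNA repair, homologous recombination"),
]:
    net.add_node(pm.Node(name=name, annotation=ann))

# TP53-MDM2 supported by three evidence channels
net.add_edge(pm.Edge(source="TP53", target="MDM2", edge_type=1, weight=0.95))  # experiments
net.add_edge(pm.Edge(source="TP53", target="MDM2", edge_type=2, weight=0.80))  # text mining
net.add_edge(pm.Edge(source="TP53", target="MDM2", edge_type=3, weight=0.40))  # co-expression
net.add_edge(pm.Edge(source="TP53", target="CDKN1A", edge_type=1, weight=0.90))
net.add_edge(pm.Edge(source="TP53", target="BRCA1", edge_type=2, weight=0.30))

s = pm.stats(net)
print(f"{s.n_nodes} nodes, {s.n_edges} edge records over {s.n_pairs} pairs")
print(f"density {s.density:.3f}, components {s.n_components}")
print(f"records per evidence channel: {s.per_type_counts}")
# 4 nodes, 5 edge records over 3 pairs: the TP53-MDM2 pair alone carries 3.

strong = pm.filter_edges(net, min_weight=0.5)
print(f"edges with confidence >= 0.5: {strong.n_edges}")

hits = pm.search(net, "DNA", fields={"annotation"})
print(f"nodes annotated with DNA-related function: {sorted(hits)}")

merged = pm.collapse(net, {"MDM2", "CDKN1A"}, "TP53_targets")
print(f"after collapsing the two regulators: {merged.node_names}")
for e in merged.edges:
    print(f"  {e.source} -[type {e.edge_type}, w={e.weight}]- {e.target}")
# Parallel external edges are merged per (neighbor, type) keeping max weight.
restored = pm.expand(merged, "TP53_targets")
print(f"expand undoes collapse exactly: {restored == net}")
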