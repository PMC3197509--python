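"""Persist a network in the medusa flat format and export it to the
interchange dialects other tools read (Pajek NET, Cytoscape SIF,
GraphViz DOT)."""

import tempfile
from pathlib import Path

import pymedusa as pm

tmp = Path(tempfile.mkdtemp())
source = tmp / "demo.medusa"
source.write_text(
    """*edges
ObpA ObpB c:1 conf:0.8
ObpA ObpB c:4 conf:0.35
ObpB ObpC c:2 conf:0.6
*nodes
ObpA c:#1f77b4 s:circle a:"odorant binding protein"
ObpB c:#d62728 s:rectangle
ObpC
"""
)

doc = pm.read_medusa(source)
print(f"loaded {doc.network.n_nodes} nodes, {doc.network.n_edges} edge records")

# Save/reload: the canonical writer round-trips everything, session included.
doc.layout = pm.layout_circular(doc.network)
saved = tmp / "session.medusa"
pm.write_medusa(doc, saved)
reloaded = pm.read_medusa(saved)
print(f"session round-trip intact: {reloaded == doc}")

print("\n--- Pajek NET (1-based ids; one line per edge record) ---")
print(pm.export_pajek(doc.network, doc.layout))
print("--- Cytoscape SIF (relation token encodes the edge type) ---")
print(pm.export_sif(doc.network))
print("--- GraphViz DOT (node styles and fixed positions carried over) ---")
print(pm.export_dot(doc.network, doc.layout))
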