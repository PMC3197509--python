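# The medusa flat-file format (normative)

This document is the normative definition of the text dialect read by
`pymedusa.read_medusa` and emitted by `pymedusa.write_medusa`.

## Graph file

A graph file is UTF-8 text made of an optional `*directed` header, an
`*edges` section and a `*nodes` section, in that order.  Both section
headers are required (either section may be empty).  Lines whose first
non-blank character is `#` are comments; blank lines are ignored.
Section headers are case-insensitive.

```
file      := [ "*directed" NL ] "*edges" NL edge-line* "*nodes" NL node-line*
edge-line := SRC WS TGT ( WS edge-attr )*
edge-attr := "c:" INT(1..8)                 ; edge type (default 1)
           | "conf:" FLOAT(0..1)            ; confidence weight (default 1.0)
           | "o:" ("up"|"down"|"straight")  ; Bezier bow override (default auto)
           | KEY ":" VALUE                  ; unknown keys preserved verbatim
node-line := NAME ( WS node-attr )*
node-attr := "c:" ( R "," G "," B | "#RRGGBB" )   ; fill color (default 180,180,180)
           | "s:" ("circle"|"rectangle"|"triangle"|"diamond"|"hexagon")
           | "x:" FLOAT(0..1) | "y:" FLOAT(0..1)  ; normalized coordinates,
                                                  ;   origin top-left, y downward
           | "a:" QUOTED                          ; annotation, may contain spaces
           | "u:" VALUE                           ; URL
           | KEY ":" VALUE                        ; unknown keys preserved verbatim
```

Tokens are whitespace-separated; the annotation value uses shell-style
double quoting (`a:"tumor suppressor"`, with `\"` and `\\` escapes).
Node names must be unique and contain no whitespace.  Edge identity is
`(source, target, type)`; for undirected files the endpoint pair is
order-normalized, and at most 8 edge records may link one node pair.

Edges may reference names never declared under `*nodes`; such nodes are
auto-created with default attributes and a warning (the historical
"edge-list only" style).  Node coordinates present in the file are
honored by the renderer, so external layout programs can pre-compute
positions.

Example:

```
*edges
TP53 MDM2 c:1 conf:0.9
TP53 MDM2 c:2 conf:0.5
TP53 BRCA1 c:3 conf:0.2 o:up
*nodes
TP53 c:#ff0000 s:circle x:0.2 y:0.4 a:"tumor suppressor" u:https://example.org/tp53
MDM2 c:0,0,255 s:rectangle
BRCA1
```

### Canonical form

The writer emits nodes in lexicographic order and edges sorted by
`(source, target, type)`, with a fixed attribute order (`c`, `conf`,
`o` for edges; `c`, `s`, `x`, `y`, `a`, `u` for nodes, then preserved
unknown attributes).  Floats are written in shortest round-trip form.
Writing a freshly parsed document therefore reproduces a canonical file
byte for byte: `write ∘ read` is idempotent.

## Session sidecar (`<file>.session`)

Session state beyond the graph — a layout, a clustering, a background
image path — is stored next to the graph file in `<file>.session` as
simple `key: value` lines, keeping the graph file interoperable:

```
background: cell.png
layout.algorithm: force_directed
layout.seed: 0
layout.coord: TP53 0.21 0.4          # one line per node: name x y
cluster.method: spectral
cluster.k: 2
cluster.assign: TP53 0               # one line per node: name cluster-id
cluster.exemplar: 0 TP53             # affinity propagation only
```

`read_medusa` loads the sidecar automatically when present.

## Cluster text file

Predefined clusterings (and `export_clusters` output) are two-column
tab-separated text, one `nodeName<TAB>clusterLabel` per line.  On
import, labels map to contiguous 0-based ids in first-appearance order;
nodes absent from the file form one trailing "unclustered" cluster.
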