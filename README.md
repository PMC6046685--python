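# coastband

Transversal continuity analysis of coastal landscapes from land-cover
polygons — an open, scriptable alternative to proprietary-GIS workflows for
coastal-zone management and landscape-connectivity studies.

## The problem

Coastal landscapes are usually analysed *longitudinally*, in fixed-width
buffer strips parallel to the shore. That zoning is blind to how natural
land cover is organised *perpendicular* to the coast: whether a beach
connects, patch by patch, to forests and wetlands deep inland, or whether a
strip of hotels cuts the hinterland off at the waterfront. `coastband`
analyses exactly that transversal structure, using the patches themselves —
not arbitrary buffer distances — as the spatial unit.

The input is a land-use/land-cover polygon layer (CORINE Land Cover Level-3
codes, e.g. `CODE_18 = "312"`) in a projected CRS, plus a coastline that can
be derived from the layer's own sea polygons.

## The method

Working on the patch contiguity graph (rook or queen adjacency, plus a
virtual coast node):

1. **Band level** `band(p)` — the adjacency order of patch *p* from the
   coastline: band 1 touches the coast, band k touches band k−1; computed as
   BFS distance from the coast node, capped at B (default 10).
2. **TCNLM** — *transversally connected natural landscape mosaics*: the
   natural patches (default 14 CLC classes: 311–313, 321, 323, 324, 331,
   333, 411, 421, 422, 521–523; optionally olive groves 223 and
   agro-forestry 244 in Mediterranean settings) linked to the coastline by a
   band-descending chain of natural patches.
3. **TCD** `tcd(p)` — *Transversal Continuity Depth*: the deepest band
   reachable from *p* through a strictly band-ascending chain of mosaic
   members, so `band(p) ≤ tcd(p) ≤ B`. A band-2 patch in a mosaic stretching
   to band 8 has TCD 8.
4. **Interpretation** — the band × TCD cross-tabulation; *endangered hinge
   patches* (low band, high TCD) whose artificialization would strand deeper
   mosaic members, verified by removal-and-recompute; and *barrier patches*:
   artificial band-1 patches whose restoration would reconnect a mosaic
   starting at band 2 to the coast.

## Worked example

```python
from coastband import (worked_example_chain, build_adjacency,
                       assign_bands, extract_tcnlm, assign_tcd)

lulc, coast = worked_example_chain(2, 8)   # natural chain, bands 1..8
graph = build_adjacency(lulc, coast)
bands = assign_bands(graph)
mosaics = extract_tcnlm(bands, graph, lulc)
tcd = assign_tcd(mosaics, bands, graph)
```

Running `python examples/02_mosaics_and_depth.py` prints:

```
chain of 8 natural patches, 8 TCNLM members
  patch r0c0: band 1, TCD 8
  patch r1c0: band 2, TCD 8
  ...
  patch r7c0: band 8, TCD 8
```

Every patch of the chain carries TCD 8: each one provides natural
continuity from the coastline down to the eighth band inland. The
hinge/barrier example (`examples/03_hinges_and_barriers.py`) plants a
single-link natural block and an artificial waterfront cell and recovers
both by computation:

```
endangered r2c2: band 3, TCD 8; artificializing it strands 5 deeper patch(es)
barrier r0c8 (clc-112): restoring it reconnects 5 natural patches down to band 6
```

The `examples/` directory holds one short script per capability; the
`coastband` command exposes the same stages from the shell
(`coastband synth | derive-coastline | bands | tcnlm | tcd | interpret | run`).

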