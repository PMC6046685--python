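"""TCNLM membership and Transversal Continuity Depth on the textbook chain.

A single column of natural patches running from the coastline to band 8 is
the canonical continuity-depth example: every patch in the chain provides
connectivity all the way down to band 8, so every patch carries TCD = 8.
"""

from coastband import (
    assign_bands,
    assign_tcd,
    build_adjacency,
    extract_tcnlm,
    worked_example_chain,
)

lulc, coast = worked_example_chain(2, 8)
graph = build_adjacency(lulc, coast)
bands = assign_bands(graph)
mosaics = extract_tcnlm(bands, graph, lulc)
tcd = assign_tcd(mosaics, bands, graph)

print(f"chain of {len(lulc)} natural patches, {len(mosaics.members)} TCNLM members")
for p in sorted(mosaics.members, key=lambda q: bands[q]):
    print(f"  patch {p}: band {bands[p]}, TCD {tcd[p]}")
# A band-2 patch in a mosaic stretching to band 8 gets TCD 8: it is two
# steps from the sea but anchors natural continuity eight bands inland.
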