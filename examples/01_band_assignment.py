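"""Band levels: how far each land-cover patch sits from the coastline.

Generates a synthetic coastal strip 12 patch-rows deep, builds the rook
contiguity graph against the seaward edge, and assigns each patch its band
level (adjacency order from the coastline, capped at 10).
"""

from coastband import SyntheticSpec, assign_bands, build_adjacency, generate

lulc, coast = generate(SyntheticSpec(rows=12, cols=5, seed=1))
graph = build_adjacency(lulc, coast, mode="rook")
bands = assign_bands(graph, B=10)

counts = {k: len(bands.patches_in_band(k)) for k in range(1, 11)}
unassigned = len(lulc) - len(bands.band)
print(f"patches: {len(lulc)}, coastline length: {coast.length:.0f} m")
print(f"patches per band 1..10: {list(counts.values())}")
print(f"max band: {bands.max_band}, unassigned (deeper than band 10): {unassigned}")
# Band k holds the patches exactly k adjacency steps inland from the coast;
# the strip is 12 rows deep, so the last two rows fall outside the 10 bands.
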