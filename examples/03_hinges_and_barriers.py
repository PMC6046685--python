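"""Hinge (endangered) and barrier patches on a landscape with planted motifs.

The hinge motif plants a natural block whose only link at band 3 is one
cell; the barrier motif puts an artificial cell on the waterfront of an
otherwise natural column.  Stage 4 should recover both by computation.
"""

from coastband import (
    Barrier,
    Hinge,
    PipelineConfig,
    SyntheticSpec,
    generate,
    run,
)

spec = SyntheticSpec(
    rows=10,
    cols=12,
    seed=7,
    class_weights={"211": 1.0},  # agricultural background: no accidental mosaics
    motifs=(Hinge(col=2, band=3, depth=8), Barrier(col=8, depth=6)),
)
lulc, coast = generate(spec)
res = run(lulc, coast, PipelineConfig(band_max=4, tcd_min=5))

print(f"TCNLM members: {res.summary['tcnlm_members']} in {res.summary['mosaics']} mosaic(s)")
for e in res.endangered:
    print(
        f"endangered {e.id}: band {e.band}, TCD {e.tcd}; artificializing it "
        f"strands {len(e.dependent_patch_ids)} deeper patch(es)"
    )
for b in res.barriers:
    print(
        f"barrier {b.id} (clc-{b.clc_code}): restoring it reconnects "
        f"{len(b.unlocked_mosaic_member_ids)} natural patches down to band {b.unlocked_depth}"
    )
# Every patch of the single-link column up to the hinge is flagged: each is
# the sole corridor for everything behind it.  The waterfront artificial
# cell is the restorable barrier in front of the natural chain.
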