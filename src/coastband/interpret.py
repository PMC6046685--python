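"""Interpretive stage: cross-tabulation, hinge patches, barrier patches.

Three read-outs of the band/TCD structure:

* **Cross-tabulation** of band level against TCD value over all mosaic
  members.  Because TCD is the deepest band reachable *inland*, TCD >= band
  always holds, so the lower triangle (TCD < band) is structurally zero.
  Members near the coast (low band) with high TCD are the crucial
  components: close to the sea yet carrying deep inland continuity.

* **Endangered (hinge) patches** — low-band, high-TCD members whose loss
  would fragment the mosaic.  The criterion is operational: artificialize
  the candidate, re-run the mosaic extraction, and flag it iff other
  members drop out (its *dependent set*).  Whether the candidate is the
  only member of its band within its mosaic is reported as an auxiliary
  flag, not the criterion.

* **Barrier patches** — artificial band-1 patches standing between the
  coastline and a natural mosaic that starts at band 2; restoring one would
  reconnect that mosaic to the coast.  Found by re-running the membership
  propagation with the band-1 seed set replaced by the coast-adjacent
  artificial patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .adjacency import COAST, neighbors
from .banding import BandAssignment
from .connectivity import (
    MosaicSet,
    NatureScheme,
    TCDAssignment,
    _natural_ids,
    _propagate_membership,
    classify_code,
    extract_tcnlm,
)
from .geoio import LandCoverMap


def cross_tabulate(
    bands: BandAssignment,
    tcd: TCDAssignment,
    lulc: LandCoverMap | None = None,
) -> pd.DataFrame:
    """Band-level x TCD-value member counts as a B x B table.

    Rows are band level, columns TCD value, entries member patch counts.
    If *lulc* is given, a parallel ``area_m2`` attribute table is attached
    via ``DataFrame.attrs``.
    """
    B = bands.B
    idx = pd.RangeIndex(1, B + 1, name="band")
    cols = pd.RangeIndex(1, B + 1, name="tcd")
    counts = pd.DataFrame(0, index=idx, columns=cols)
    areas = pd.DataFrame(0.0, index=idx, columns=cols)
    for p, t in tcd.tcd.items():
        b = bands[p]
        counts.loc[b, t] += 1
        if lulc is not None:
            areas.loc[b, t] += lulc[p].area
    if lulc is not None:
        counts.attrs["area_m2"] = areas
    return counts


@dataclass(frozen=True)
class EndangeredPatch:
    """One flagged hinge patch and the members that depend on it."""

    id: str
    band: int
    tcd: int
    mosaic_id: int
    dependent_patch_ids: frozenset[str]
    unique_in_band_within_mosaic: bool


@dataclass(frozen=True)
class BarrierPatch:
    """One artificial waterfront patch blocking a mosaic from the coast."""

    id: str
    clc_code: str
    unlocked_mosaic_member_ids: frozenset[str]
    unlocked_depth: int


def find_endangered(
    mosaics: MosaicSet,
    bands: BandAssignment,
    graph: nx.Graph,
    tcd: TCDAssignment,
    lulc: LandCoverMap,
    scheme: NatureScheme = NatureScheme(),
    band_max: int = 4,
    tcd_min: int = 7,
    lateral_merge: bool = False,
) -> list[EndangeredPatch]:
    """Flag hinge members whose artificialization fragments the mosaic.

    Candidates are members with band <= *band_max* and TCD >= *tcd_min*
    (defaults: bands 1-4, TCD 7-10).  Each candidate is re-tested by
    removing it from the natural set and re-running the mosaic extraction;
    it is flagged iff members other than itself are lost.
    """
    if band_max >= tcd_min:
        warnings.warn(
            f"band_max ({band_max}) >= tcd_min ({tcd_min}): the screen is vacuous "
            f"(every member has TCD >= band)",
            stacklevel=2,
        )
    candidates = sorted(
        p for p in mosaics.members if bands[p] <= band_max and tcd[p] >= tcd_min
    )
    natural = _natural_ids(lulc, scheme)
    seed_full = {p for p in bands.patches_in_band(1) if p in natural and graph.has_edge(p, COAST)}

    flagged: list[EndangeredPatch] = []
    for cand in candidates:
        nat = natural - {cand}
        seed = seed_full - {cand}
        members = _propagate_membership(seed, nat, bands, graph, lateral_merge)
        dependents = mosaics.members - members - {cand}
        if not dependents:
            continue
        mosaic = mosaics.mosaic_id[cand]
        unique = not any(
            q != cand and mosaics.mosaic_id.get(q) == mosaic and bands[q] == bands[cand]
            for q in mosaics.members
        )
        flagged.append(
            EndangeredPatch(
                id=cand,
                band=bands[cand],
                tcd=tcd[cand],
                mosaic_id=mosaic,
                dependent_patch_ids=frozenset(dependents),
                unique_in_band_within_mosaic=unique,
            )
        )
    return flagged


def find_barriers(
    lulc: LandCoverMap,
    bands: BandAssignment,
    graph: nx.Graph,
    scheme: NatureScheme = NatureScheme(),
    exclude_already_connected: bool = False,
) -> list[BarrierPatch]:
    """Flag artificial band-1 patches that lock natural mosaics off the coast.

    The membership propagation of the mosaic extraction is re-run with the
    band-1 seed set replaced by the coast-adjacent *artificial* patches;
    bands >= 2 propagate through natural patches exactly as usual.  A seed
    is flagged iff it touches at least one natural band-2 patch reached
    this way.  With ``exclude_already_connected``, band-2 patches that are
    already mosaic members through natural band-1 links are ignored when
    deciding flags, isolating patches that are the sole separation.

    ``unlocked_depth`` is the deepest band among the members reached behind
    each flagged patch.
    """
    natural = _natural_ids(lulc, scheme)
    already = (
        extract_tcnlm(bands, graph, lulc, scheme).members
        if exclude_already_connected
        else frozenset()
    )

    seeds = sorted(
        p.id
        for p in lulc.active_patches
        if classify_code(p.clc_code, scheme) == "artificial"
        and bands[p.id] == 1
        and graph.has_edge(p.id, COAST)
    )

    flagged: list[BarrierPatch] = []
    for s in seeds:
        reached = _propagate_membership({s}, natural | {s}, bands, graph)
        reached -= {s}
        band2 = {p for p in reached if bands[p] == 2 and graph.has_edge(s, p)}
        if exclude_already_connected:
            band2 -= already
        if not band2:
            continue
        flagged.append(
            BarrierPatch(
                id=s,
                clc_code=lulc[s].clc_code,
                unlocked_mosaic_member_ids=frozenset(reached),
                unlocked_depth=max(bands[p] for p in reached),
            )
        )
    return flagged
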