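# Methods

## Model

The unit of analysis is the land-cover *patch*: a simple polygon with a
3-digit CORINE Level-3 class code, in a projected CRS with metre units. All
spatial reasoning happens on one object, the **adjacency graph**: nodes are
patch ids plus a virtual `COAST` node; an edge connects two patches (or a
patch and the coast) when the contiguity predicate holds, and carries the
shared boundary length in metres.

Two predicates are offered:

* **rook** (default): shared boundary of positive length, i.e.
  `length(∂p ∩ ∂q) > min_shared_boundary`. Corner-only contact does not
  count — a point contact is no ecological corridor.
* **queen**: any boundary intersection, matching a GIS "intersect"
  selection. Provided because the original desktop-GIS phrasing of the
  selection step does not pin down corner contacts; both modes are first-
  class so replications can test either.

`min_shared_boundary` (metres, default 0) suppresses sliver contacts in
real land-cover exports; 25 m is a practical value for CORINE-scale data.

### Stage 1 — band levels

`band(p)` is the BFS hop distance from `COAST`, capped at the band limit
`B` (default 10, the conventional analysis depth; it is a parameter because
study areas differ in depth). BFS is provably identical to the operational
formulation — select patches touching the coast, export as band 1, select
patches touching band 1 among the rest, export as band 2, … — and that
iterative select-and-erase version is kept in the test suite as an
independent oracle, not as the production path. Patches deeper than B or
disconnected from the coast stay **unassigned** (exported as band 0) rather
than being dropped, so the input partition survives re-runs with larger B.

### Stage 2 — TCNLM membership

Natural patches are those in the active nature scheme: by default the 14
CLC classes 311, 312, 313, 321, 323, 324, 331, 333, 411, 421, 422, 521,
522, 523; the Mediterranean option adds 223 (olive groves) and 244
(agro-forestry). Membership propagates strictly band-ascending: band-1
natural patches touching the coastline seed the set; a natural band-k patch
joins iff it touches a member of band k−1. Same-band (lateral) adjacency
does **not** propagate membership by default, because transversal
connectivity is defined between consecutive bands only; `lateral_merge`
optionally closes each band's membership under same-band natural adjacency
for users who want laterally merged mosaics. Mosaic ids label connected
components of the member subgraph (which does include lateral edges — a
component is a component), numbered in ascending order of each component's
smallest patch id for determinism.

### Stage 3 — Transversal Continuity Depth

`tcd(p)` = the maximum band reachable from member *p* by a strictly
band-ascending chain of members. The production algorithm is the descending
sweep: for t = B…1, seed still-unlabelled members of band t with TCD = t
and push the label coastward through adjacent members of bands t−1, …, 1.
The sweep and the chain formalisation are provably equivalent (the sweep
labels p with the largest t whose descending frontier reaches p, which is
exactly the deepest ascending chain from p); the exhaustive ascending-chain
search is kept as the test oracle. Members only; non-members carry no TCD.
The assignment is order-independent because each sweep step is a whole-band
set operation.

### Stage 4A — cross-tab and hinge patches

The cross-tabulation counts members by (band, TCD); since TCD ≥ band its
lower triangle is structurally zero. Hinge candidates are members with
band ≤ 4 and TCD ≥ 7 (both user-settable: descriptions of hinge positions
range from low to middle bands depending on the landscape). The hinge
*criterion* is operational: artificialize the candidate, re-run Stage 2,
and flag it iff other members drop out; those lost members are its
dependent set. The alternative reading — "only member of its band within
its mosaic" — is computed as an auxiliary flag because it identifies
uniqueness, not fragmentation. The removal test is the definition; the
full-recompute check in the tests is therefore a self-consistency oracle.

### Stage 4B — barrier patches

Stage 2's propagation is re-run with the band-1 seed set replaced by the
coast-adjacent *artificial* patches, propagating through natural patches
from band 2 on. An artificial seed touching at least one natural band-2
patch reached this way is a barrier; `unlocked_depth` is the deepest band
among the patches behind it. By default the run is exactly the Stage-2
machinery with a different seed filter; `exclude_already_connected`
additionally ignores band-2 patches that are already mosaic members via
natural band-1 links, isolating barriers that are the sole separation.

## Coastline derivation (Stage 0)

Sea mode dissolves the patches of the sea classes (default 523) and
intersects that union with the union of all other patches; the linear
components of the intersection are the coastline. Sea patches are then
excluded from banding — although 523 appears in the natural class list, a
polygon used to *define* the coastline cannot also be a band-1 patch; the
`keep_sea_patches` flag restores the literal all-natural reading for users
who band offshore water. Split-point mode dissolves everything to one
polygon, converts the outline to a ring and returns the path between the
two outline points nearest the given coordinates (`side` selects the
shorter or longer arc).

Invalid geometries are repaired with `shapely.make_valid` rather than a
zero-width buffer: a buffer(0) silently discards one lobe of a
self-crossing ring, while make_valid preserves the full area. Irreparable
features are rejected with their ids. Geographic (degree-based) CRSs are
rejected unless explicitly allowed, because every length threshold is
metric.

## Synthetic fixtures

The generator emulates a coastal strip as a rows × cols grid of square
patches (default cell 100 m) whose seaward edge is the coastline, with
class codes drawn from a configurable weight table by a seeded PCG64
generator, and deterministic motifs stamped on top: `corridor` (a natural
chain to a stated depth), `hinge` (a natural block whose only link at a
stated band is one cell) and `barrier` (an artificial waterfront cell
fronting a natural chain). The default class mixture (~60 % natural, ~25 %
agricultural, ~15 % artificial) reflects a moderately developed coastal
zone. On a full grid, band = row index + 1 in closed form, which anchors
the generator's own tests.

What the grid does *not* emulate: realistic patch-size distributions,
irregular patch shapes, spatial autocorrelation of classes, or CORINE's
25 ha minimum mapping unit. Passing tests therefore demonstrate
correctness of the graph algorithms and filters under controlled topology,
not robustness to the geometric pathologies of real exports (which the
repair and `min_shared_boundary` options address separately).

Oracle-equivalence tests run the pipeline against brute-force
reimplementations (all-pairs adjacency, select-and-erase banding,
exhaustive chain searches) on 200 seeded random landscapes of ≤100 patches
with randomly deleted cells — small enough that exhaustive search is exact,
varied enough to hit disconnected, dead-end and beyond-limit topologies.

## Numerical and design notes

* Geometry predicates use shapely's native tolerance; no custom snapping.
* The STRtree spatial index only prunes candidates; the edge set is
  defined by the exact predicates and verified against all-pairs testing.
* All outputs are deterministic: mosaic ids by smallest-member order, JSON
  with sorted keys, no timestamps; identical config + input ⇒
  byte-identical files.
* Vector I/O is GeoJSON (with a legacy named-CRS member passed through
  verbatim); tables are CSV. Multi-part features are exploded by default
  because a band level belongs to a contiguous patch.
* Degenerate inputs: an empty band 1 yields a warning and an all-unassigned
  map; an all-artificial map yields an empty mosaic set, a zero cross-tab
  and no flags; `band_max ≥ tcd_min` warns that the hinge screen is
  vacuous but still runs.

## Limitations

* No distance-based (non-contiguous) neighbour rules and no weighted
  connectivity indices; adjacency is strictly topological.
* No reprojection: inputs must already share one projected CRS.
* Shapefile/GeoPackage are not read directly; convert to GeoJSON first.
* The hinge removal test is single-patch; compound hinges (two patches
  that only fail jointly) are not flagged.
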