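"""Natural-surface filtering, mosaic extraction and continuity depth.

Two operations form the analytical core of the method:

**TCNLM extraction** — starting from the natural patches that touch the
coastline (band 1), membership in a *transversally connected natural
landscape mosaic* propagates band by band inland: a natural band-k patch is
a member iff it touches a member of band k-1.  Natural patches whose only
seaward neighbours are artificial or agricultural are excluded — they have
no transversal connection to the coast.

**TCD assignment** — each mosaic member is then labelled with its
*Transversal Continuity Depth*: the deepest band it provides transversal
connectivity for.  The production algorithm is a descending sweep: seed the
still-unlabelled members of band t with TCD = t, then push the label t
coastward through adjacent members of band t-1, t-2, ..., 1; repeat for
t = B down to 1.  Equivalently, TCD(p) is the maximum band reachable from p
by a strictly band-ascending chain of members — a band-1 member fronting a
mosaic that stretches to band 8 gets TCD 8, while a lone coastal member
with no band-2 connection gets TCD 1.

Classification of codes follows the CORINE Level-3 nomenclature: 1xx
artificial, 2xx agricultural; the default natural set is the standard
14-class list (water bodies, wetlands, forests and semi-natural classes).
In Mediterranean contexts olive groves (223) and agro-forestry (244) may be
counted as natural via ``mediterranean_extras``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .adjacency import COAST, neighbors
from .banding import BandAssignment
from .errors import ConfigurationError, InternalConsistencyError
from .geoio import CLC_CODE_RE, LandCoverMap

#: Default natural CLC Level-3 classes: marine/inland waters (5xx), wetlands
#: (4xx), and the forest & semi-natural group (3xx) minus burnt/bare classes.
DEFAULT_NATURAL_CODES = frozenset(
    {"523", "522", "521", "422", "421", "411", "333", "331", "324", "323", "321", "313", "312", "311"}
)

#: Mediterranean additions: olive groves and agro-forestry.
MEDITERRANEAN_EXTRAS = frozenset({"223", "244"})


@dataclass(frozen=True)
class NatureScheme:
    """Which class codes count as natural surfaces.

    ``mediterranean_extras`` adds olive groves (223) and agro-forestry (244)
    to the natural set, overriding their agricultural prefix.
    """

    natural_codes: frozenset[str] = DEFAULT_NATURAL_CODES
    mediterranean_extras: bool = False

    @property
    def effective_natural(self) -> frozenset[str]:
        if self.mediterranean_extras:
            return self.natural_codes | MEDITERRANEAN_EXTRAS
        return self.natural_codes


def classify_code(code: str, scheme: NatureScheme = NatureScheme()) -> str:
    """Classify a 3-digit code as natural / artificial / agricultural / other.

    Natural membership (including enabled extras) takes precedence over the
    prefix rules; otherwise leading digit 1 is artificial and 2 agricultural.
    """
    code = str(code)
    if not CLC_CODE_RE.match(code):
        raise ConfigurationError(f"malformed class code {code!r}")
    if code in scheme.effective_natural:
        return "natural"
    if code[0] == "1":
        return "artificial"
    if code[0] == "2":
        return "agricultural"
    return "other"


@dataclass(frozen=True)
class MosaicSet:
    """TCNLM membership plus connected-component mosaic labels."""

    members: frozenset[str]
    mosaic_id: dict[str, int]

    def __contains__(self, patch_id: str) -> bool:
        return patch_id in self.members


@dataclass(frozen=True)
class TCDAssignment:
    """Member patch id -> Transversal Continuity Depth in band(p)..B."""

    tcd: dict[str, int]

    def __getitem__(self, patch_id: str) -> int:
        return self.tcd[patch_id]


def _natural_ids(lulc: LandCoverMap, scheme: NatureScheme, treat_artificial: frozenset[str] = frozenset()) -> set[str]:
    return {
        p.id
        for p in lulc.patches
        if p.id not in treat_artificial and classify_code(p.clc_code, scheme) == "natural"
    }


def _propagate_membership(
    seed: set[str],
    natural: set[str],
    bands: BandAssignment,
    graph: nx.Graph,
    lateral_merge: bool = False,
) -> set[str]:
    """Band-ascending membership propagation from a band-1 seed set."""
    members = set(seed)
    prev = set(seed)
    for k in range(2, bands.B + 1):
        level = {p for p in bands.patches_in_band(k) if p in natural}
        added = {p for p in level if any(q in prev for q in neighbors(graph, p))}
        if lateral_merge:
            # lateral closure: natural same-band patches touching a member
            frontier = set(added)
            while frontier:
                nxt = {
                    q
                    for p in frontier
                    for q in neighbors(graph, p)
                    if q in level and q not in added
                }
                added |= nxt
                frontier = nxt
        members |= added
        prev = added
    return members


def extract_tcnlm(
    bands: BandAssignment,
    graph: nx.Graph,
    lulc: LandCoverMap,
    scheme: NatureScheme = NatureScheme(),
    lateral_merge: bool = False,
) -> MosaicSet:
    """Extract the transversally connected natural landscape mosaics.

    A patch is a member iff it is natural under *scheme* and either lies in
    band 1 (coast-adjacent) or touches a member of the preceding band;
    computed by ascending the bands 1..B.  With ``lateral_merge`` on,
    same-band natural patches touching a member of that band also join —
    off by default, since transversal connectivity only ever tests band k
    against band k-1.

    Mosaic ids label the connected components of the member subgraph,
    assigned in ascending order of each component's smallest patch id.
    """
    natural = _natural_ids(lulc, scheme)
    seed = {p for p in bands.patches_in_band(1) if p in natural and graph.has_edge(p, COAST)}
    members = _propagate_membership(seed, natural, bands, graph, lateral_merge)

    sub = graph.subgraph(members)
    comps = sorted(nx.connected_components(sub), key=lambda c: min(c))
    mosaic_id = {p: i + 1 for i, comp in enumerate(comps) for p in comp}
    return MosaicSet(frozenset(members), mosaic_id)


def assign_tcd(
    mosaics: MosaicSet,
    bands: BandAssignment,
    graph: nx.Graph,
) -> TCDAssignment:
    """Assign every mosaic member its Transversal Continuity Depth.

    Descending sweep: for t = B..1, seed the still-unlabelled members of
    band t with TCD = t, then propagate t coastward — an unlabelled member
    of band k touching a TCD-t member of band k+1 receives t, for
    k = t-1 down to 1.  Every member ends labelled; the result is
    independent of patch enumeration order because each sweep is a set
    operation over whole bands.
    """
    for p in mosaics.members:
        if bands[p] < 1:
            raise InternalConsistencyError(f"mosaic member {p!r} has no band")

    tcd: dict[str, int] = {}
    by_band: dict[int, set[str]] = {}
    for p in mosaics.members:
        by_band.setdefault(bands[p], set()).add(p)

    for t in range(bands.B, 0, -1):
        frontier = {p for p in by_band.get(t, set()) if p not in tcd}
        for p in frontier:
            tcd[p] = t
        for k in range(t - 1, 0, -1):
            nxt = {
                p
                for p in by_band.get(k, set())
                if p not in tcd and any(q in frontier for q in neighbors(graph, p))
            }
            for p in nxt:
                tcd[p] = t
            frontier = nxt
    return TCDAssignment(tcd)
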