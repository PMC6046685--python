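"""Vector I/O and coastline derivation.

The analysis operates on a *land-cover map*: a set of non-overlapping
polygonal patches in a projected (metric) coordinate system, each carrying a
3-digit CORINE Land Cover (CLC) Level-3 class code.  This module reads such
layers from GeoJSON, validates and repairs geometry, derives the coastline
(either as the shared border between sea-class patches and everything else,
or by splitting the dissolved study-area outline between two coordinates),
and writes the analysis results back out as GeoJSON plus CSV tables.

GeoJSON is the supported vector format; it is the open text format the rest
of the toolchain (shapely's dict interchange) maps onto directly.  A legacy
``crs`` member of the form ``{"type": "Name", "properties": {"name": ...}}``
is honoured as an opaque CRS descriptor and passed through to outputs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import LineString, MultiLineString, MultiPolygon, Point, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import linemerge, unary_union

from .errors import (
    ConfigurationError,
    CRSError,
    EmptyCoastlineError,
    EmptyInputError,
    FormatError,
    GeometryError,
    SchemaError,
)

CLC_CODE_RE = re.compile(r"^[1-5][0-9][0-9]$")

#: CRS names treated as geographic (degree units) and rejected by default.
_GEOGRAPHIC_CRS_NAMES = {
    "epsg:4326",
    "urn:ogc:def:crs:epsg::4326",
    "urn:ogc:def:crs:ogc:1.3:crs84",
    "crs84",
    "wgs84",
    "ogc:crs84",
}


@dataclass(frozen=True)
class Patch:
    """One land-cover polygon, the atomic unit of every stage.

    Parameters
    ----------
    id : str
        Stable identifier, unique within a :class:`LandCoverMap`.
    geometry : shapely.Polygon
        Simple valid polygon in planar map units (metres).
    clc_code : str
        3-digit class code, e.g. ``"312"`` (coniferous forest).
    """

    id: str
    geometry: Polygon
    clc_code: str

    @property
    def area(self) -> float:
        """Patch area in square metres (derived from the geometry)."""
        return self.geometry.area

    def __post_init__(self) -> None:
        if not CLC_CODE_RE.match(self.clc_code):
            raise GeometryError(
                f"patch {self.id!r}: class code {self.clc_code!r} does not match "
                f"the 3-digit CLC pattern [1-5][0-9][0-9]"
            )
        if self.geometry.is_empty or self.geometry.area <= 0:
            raise GeometryError(f"patch {self.id!r}: geometry has no positive area")


@dataclass
class LandCoverMap:
    """A collection of patches sharing one projected CRS.

    ``excluded_ids`` holds patches removed from all banding (typically sea
    polygons once the coastline has been derived from them).
    """

    patches: list[Patch]
    crs_descriptor: str | None = None
    code_field: str = "CODE_18"
    excluded_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patches]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GeometryError(f"duplicate patch ids: {dupes[:10]}")
        self._by_id = {p.id: p for p in self.patches}

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def __getitem__(self, patch_id: str) -> Patch:
        return self._by_id[patch_id]

    def __contains__(self, patch_id: str) -> bool:
        return patch_id in self._by_id

    @property
    def active_patches(self) -> list[Patch]:
        """Patches that take part in banding (non-excluded)."""
        return [p for p in self.patches if p.id not in self.excluded_ids]

    def codes(self) -> dict[str, str]:
        """Mapping patch id -> class code."""
        return {p.id: p.clc_code for p in self.patches}


@dataclass(frozen=True)
class Coastline:
    """The coastline polyline (possibly multi-part), in planar units."""

    geometry: LineString | MultiLineString

    @property
    def length(self) -> float:
        return self.geometry.length

    def __post_init__(self) -> None:
        if self.geometry.is_empty or self.geometry.length <= 0:
            raise EmptyCoastlineError("coastline has zero length")


# ---------------------------------------------------------------------------
# reading


def _crs_name(obj: Mapping) -> str | None:
    crs = obj.get("crs")
    if not crs:
        return None
    try:
        return str(crs["properties"]["name"])
    except (KeyError, TypeError):
        return str(crs)


def _is_geographic(name: str | None) -> bool:
    return name is not None and name.strip().lower() in _GEOGRAPHIC_CRS_NAMES


def _repair(geom: BaseGeometry, feature_id: str) -> list[Polygon]:
    """Return valid simple polygons for *geom*, repaired area-preservingly.

    Bow-ties and self-touches common in land-cover exports become valid
    (possibly multi-part) polygons via ``make_valid`` — unlike a zero-width
    buffer it keeps both lobes of a self-crossing ring.  Anything that
    cannot be coerced to positive-area polygons is rejected.
    """
    if not geom.is_valid:
        from shapely.validation import make_valid

        geom = make_valid(geom)
    polys: list[Polygon] = []
    if isinstance(geom, Polygon):
        polys = [geom]
    elif isinstance(geom, MultiPolygon):
        polys = list(geom.geoms)
    elif geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if isinstance(g, Polygon)]
    polys = [p for p in polys if p.area > 0]
    if not polys:
        raise GeometryError(f"feature {feature_id!r}: geometry irreparable (no positive-area polygon)")
    return polys


def read_lulc(
    path: str | Path,
    code_field: str = "CODE_18",
    explode_multiparts: bool = True,
    allow_geographic: bool = False,
    id_field: str | None = None,
) -> LandCoverMap:
    """Read a land-cover polygon layer from a GeoJSON file.

    Multi-part features are split into single-part patches with ``_<k>``
    suffixed ids (band level is a property of a contiguous patch, so one
    multi-part feature could straddle several bands).  Invalid geometries are
    repaired by zero-width buffering; irreparable features raise with their
    feature ids.

    Parameters
    ----------
    path : path to a GeoJSON FeatureCollection of polygonal features.
    code_field : property holding the 3-digit class code (CLC dialects vary:
        ``"CODE_18"``, ``"code_12"``, ...).
    explode_multiparts : split MultiPolygons into one patch per part.
    allow_geographic : accept a layer whose CRS is geographic (degrees).
        Off by default because all length thresholds are metric.
    id_field : property to use as the patch id; defaults to the feature's
        ``id`` member or its position (``f<i>``).
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    if not feats:
        raise EmptyInputError(f"{path}: layer contains no features")

    crs_name = _crs_name(doc)
    if _is_geographic(crs_name) and not allow_geographic:
        raise CRSError(
            f"{path}: CRS {crs_name!r} is geographic; the analysis needs a "
            f"projected CRS in metres (pass allow_geographic to override)"
        )

    patches: list[Patch] = []
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if code_field not in props:
            raise SchemaError(
                f"{path}: feature {i} lacks code attribute {code_field!r}; "
                f"available fields: {sorted(props)}"
            )
        if id_field is not None:
            fid = str(props[id_field])
        else:
            fid = str(feat.get("id", f"f{i}"))
        geom = shape(feat["geometry"])
        parts = _repair(geom, fid)
        if explode_multiparts and len(parts) > 1:
            for k, part in enumerate(parts):
                patches.append(Patch(f"{fid}_{k}", part, str(props[code_field])))
        else:
            merged = parts[0] if len(parts) == 1 else unary_union(parts)
            patches.append(Patch(fid, merged, str(props[code_field])))

    return LandCoverMap(patches, crs_descriptor=crs_name, code_field=code_field)


def read_coastline(path: str | Path) -> Coastline:
    """Read a coastline polyline layer (GeoJSON) as a single (multi)line."""
    with open(Path(path)) as fh:
        doc = json.load(fh)
    geoms = []
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
    elif doc.get("type") == "Feature":
        geoms = [shape(doc["geometry"])]
    else:
        geoms = [shape(doc)]
    merged = unary_union(geoms)
    if isinstance(merged, MultiLineString):
        merged = linemerge(merged)
    return Coastline(merged)


# ---------------------------------------------------------------------------
# coastline derivation


def _as_line(geom: BaseGeometry) -> LineString | MultiLineString:
    """Keep only the linear components of a geometry."""
    if isinstance(geom, (LineString, MultiLineString)):
        return geom
    if geom.geom_type == "GeometryCollection":
        lines = [g for g in geom.geoms if isinstance(g, (LineString, MultiLineString))]
        if lines:
            merged = linemerge(unary_union(lines))
            return merged
    raise EmptyCoastlineError("no linear boundary component found")


def derive_coastline(
    lulc: LandCoverMap,
    sea_codes: Iterable[str] | None = None,
    split_points: Sequence[Sequence[float]] | None = None,
    side: str = "shorter",
    keep_sea_patches: bool = False,
) -> Coastline:
    """Derive the coastline polyline from the land-cover map itself.

    Two modes:

    *sea mode* (``sea_codes`` given) — the coastline is the dissolved shared
    border between the union of sea-class patches (e.g. clc-523) and the
    union of everything else.  The sea patches are marked excluded from all
    later banding unless ``keep_sea_patches`` is set.

    *split-point mode* (``split_points`` given) — all patches are dissolved
    to one polygon, its outline converted to a line and split at the two
    outline points nearest the given coordinates; the ``side`` option picks
    which of the two resulting outline paths is the coastline
    (``"shorter"`` or ``"longer"``).
    """
    sea_codes = {str(c) for c in sea_codes} if sea_codes else set()
    if not sea_codes and split_points is None:
        raise ConfigurationError("derive_coastline needs sea_codes or split_points")

    if sea_codes:
        sea = [p for p in lulc.patches if p.clc_code in sea_codes]
        if not sea:
            raise ConfigurationError(f"no patch carries a sea code {sorted(sea_codes)}")
        land = [p for p in lulc.patches if p.clc_code not in sea_codes]
        if not land:
            raise EmptyInputError("all patches are sea; nothing to band")
        sea_union = unary_union([p.geometry for p in sea])
        land_union = unary_union([p.geometry for p in land])
        shared = sea_union.intersection(land_union)
        try:
            line = _as_line(shared)
        except EmptyCoastlineError:
            raise EmptyCoastlineError("sea and land unions share no boundary") from None
        if not keep_sea_patches:
            lulc.excluded_ids.update(p.id for p in sea)
        return Coastline(line)

    if len(split_points) != 2:
        raise ConfigurationError("split_points must be exactly two (x, y) pairs")
    dissolved = unary_union([p.geometry for p in lulc.patches])
    if isinstance(dissolved, MultiPolygon):
        dissolved = max(dissolved.geoms, key=lambda g: g.area)
    ring = LineString(dissolved.exterior.coords)
    total = ring.length
    d0 = ring.project(Point(*split_points[0]))
    d1 = ring.project(Point(*split_points[1]))
    if abs(d0 - d1) < 1e-12:
        raise ConfigurationError("split points project to the same outline location")
    lo, hi = sorted((d0, d1))
    from shapely.ops import substring

    inner = substring(ring, lo, hi)
    outer_parts = [
        part
        for part in (substring(ring, 0, lo), substring(ring, hi, total))
        if part.length > 0
    ]
    outer = outer_parts[0] if len(outer_parts) == 1 else linemerge(unary_union(outer_parts))
    shorter, longer = sorted((inner, outer), key=lambda g: g.length)
    if side == "shorter":
        return Coastline(shorter)
    if side == "longer":
        return Coastline(longer)
    raise ConfigurationError(f"side must be 'shorter' or 'longer', got {side!r}")


# ---------------------------------------------------------------------------
# writing

#: result attribute names written per feature, in output order
RESULT_FIELDS = ("band", "tcnlm", "mosaic_id", "tcd", "endangered", "barrier")


def write_outputs(
    lulc: LandCoverMap,
    attributes: pd.DataFrame | Mapping[str, Mapping[str, int]],
    path: str | Path,
    fmt: str = "geojson",
) -> Path:
    """Write the map with per-patch result attributes as a vector layer.

    ``attributes`` is a table keyed by patch id with any subset of the
    columns ``band``, ``tcnlm``, ``mosaic_id``, ``tcd``, ``endangered``,
    ``barrier``.  Patches absent from the table get no result properties.
    """
    if fmt.lower() not in {"geojson", "json"}:
        raise FormatError(f"unknown output format {fmt!r}; supported: geojson")
    if not isinstance(attributes, pd.DataFrame):
        attributes = pd.DataFrame.from_dict(dict(attributes), orient="index")
    path = Path(path)

    features = []
    for p in lulc.patches:
        props = {"id": p.id, lulc.code_field: p.clc_code}
        if p.id in attributes.index:
            row = attributes.loc[p.id]
            for col in RESULT_FIELDS:
                if col in attributes.columns and pd.notna(row[col]):
                    props[col] = int(row[col])
        features.append(
            {
                "type": "Feature",
                "id": p.id,
                "properties": props,
                "geometry": mapping(p.geometry),
            }
        )
    doc: dict = {"type": "FeatureCollection", "features": features}
    if lulc.crs_descriptor:
        doc["crs"] = {"type": "Name", "properties": {"name": lulc.crs_descriptor}}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")
    return path


def write_coastline(coast: Coastline, path: str | Path, crs_descriptor: str | None = None) -> Path:
    """Write the coastline as a single-feature GeoJSON layer."""
    path = Path(path)
    doc: dict = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "id": "coastline",
                "properties": {"length_m": coast.length},
                "geometry": mapping(coast.geometry),
            }
        ],
    }
    if crs_descriptor:
        doc["crs"] = {"type": "Name", "properties": {"name": crs_descriptor}}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")
    return path
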