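"""End-to-end pipeline: coastline -> bands -> mosaics -> TCD -> reports.

Each stage consumes the previous stage's output; :func:`run_pipeline` wires
them together, writes the result layers (GeoJSON), the band x TCD
cross-tabulation (CSV) and a JSON run summary with per-stage patch counts.
Given the same configuration and input, two runs produce byte-identical
files: nothing in the pipeline depends on iteration order or wall-clock
time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .adjacency import build_adjacency
from .banding import DEFAULT_BAND_COUNT, assign_bands
from .connectivity import NatureScheme, assign_tcd, extract_tcnlm
from .errors import ConfigurationError
from .geoio import (
    Coastline,
    LandCoverMap,
    derive_coastline,
    read_coastline,
    read_lulc,
    write_coastline,
    write_outputs,
)
from .interpret import cross_tabulate, find_barriers, find_endangered


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with their defaults.

    ``sea_codes`` selects the patches the coastline is dissolved from (sea
    mode); alternatively ``coastline_path`` points at a ready-made polyline
    layer.  Remaining fields mirror the per-stage function parameters.
    """

    code_field: str = "CODE_18"
    sea_codes: tuple[str, ...] = ("523",)
    coastline_path: str | None = None
    keep_sea_patches: bool = False
    allow_geographic: bool = False
    bands: int = DEFAULT_BAND_COUNT
    adjacency_mode: str = "rook"
    min_shared_boundary: float = 0.0
    mediterranean_extras: bool = False
    natural_extra_codes: tuple[str, ...] = ()
    lateral_merge: bool = False
    band_max: int = 4
    tcd_min: int = 7
    exclude_already_connected: bool = False

    def validate(self) -> None:
        if self.bands < 1:
            raise ConfigurationError("bands must be >= 1")
        if self.adjacency_mode not in ("rook", "queen"):
            raise ConfigurationError(f"adjacency_mode must be rook|queen, got {self.adjacency_mode!r}")
        if self.min_shared_boundary < 0:
            raise ConfigurationError("min_shared_boundary must be >= 0")
        if not self.sea_codes and self.coastline_path is None:
            raise ConfigurationError("need sea_codes or coastline_path to obtain a coastline")

    def scheme(self) -> NatureScheme:
        base = NatureScheme(mediterranean_extras=self.mediterranean_extras)
        if self.natural_extra_codes:
            base = dataclasses.replace(
                base, natural_codes=base.natural_codes | frozenset(self.natural_extra_codes)
            )
        return base


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    lulc: LandCoverMap
    coastline: Coastline
    graph: object
    bands: object
    mosaics: object
    tcd: object
    crosstab: pd.DataFrame
    endangered: list
    barriers: list
    summary: dict


def run(
    lulc: LandCoverMap,
    coastline: Coastline,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run Stages 1-4 on in-memory inputs (the library entry point)."""
    config.validate()
    scheme = config.scheme()
    graph = build_adjacency(lulc, coastline, config.adjacency_mode, config.min_shared_boundary)
    bands = assign_bands(graph, config.bands)
    mosaics = extract_tcnlm(bands, graph, lulc, scheme, config.lateral_merge)
    tcd = assign_tcd(mosaics, bands, graph)
    crosstab = cross_tabulate(bands, tcd, lulc)
    endangered = find_endangered(
        mosaics, bands, graph, tcd, lulc, scheme,
        config.band_max, config.tcd_min, config.lateral_merge,
    )
    barriers = find_barriers(lulc, bands, graph, scheme, config.exclude_already_connected)

    band_counts = {
        str(k): sum(1 for b in bands.band.values() if b == k)
        for k in range(1, config.bands + 1)
    }
    summary = {
        "software": "coastband",
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "patches_total": len(lulc),
        "patches_banded": len(bands.band),
        "band_counts": band_counts,
        "max_band": bands.max_band,
        "tcnlm_members": len(mosaics.members),
        "mosaics": len(set(mosaics.mosaic_id.values())),
        "max_tcd": max(tcd.tcd.values(), default=0),
        "endangered_count": len(endangered),
        "barrier_count": len(barriers),
    }
    return PipelineResult(lulc, coastline, graph, bands, mosaics, tcd, crosstab, endangered, barriers, summary)


def result_table(res: PipelineResult) -> pd.DataFrame:
    """Per-patch attribute table (band, tcnlm, mosaic_id, tcd, flags)."""
    endangered_ids = {e.id for e in res.endangered}
    barrier_ids = {b.id for b in res.barriers}
    rows = {}
    for p in res.lulc.patches:
        member = p.id in res.mosaics.members
        rows[p.id] = {
            "band": res.bands[p.id],
            "tcnlm": int(member),
            "mosaic_id": res.mosaics.mosaic_id.get(p.id, 0),
            "tcd": res.tcd.tcd.get(p.id, 0),
            "endangered": int(p.id in endangered_ids),
            "barrier": int(p.id in barrier_ids),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "id"
    return table


def run_pipeline(
    config: PipelineConfig,
    input_path: str | Path,
    out_dir: str | Path,
) -> PipelineResult:
    """Execute Stage 0 through 4B from an input layer to an output directory.

    Writes ``coastline.geojson``, ``result.geojson`` (all patches with band /
    tcnlm / mosaic_id / tcd / endangered / barrier attributes),
    ``crosstab.csv`` and ``summary.json``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lulc = read_lulc(input_path, config.code_field, allow_geographic=config.allow_geographic)
    if config.coastline_path is not None:
        coastline = read_coastline(config.coastline_path)
    else:
        coastline = derive_coastline(
            lulc, sea_codes=config.sea_codes, keep_sea_patches=config.keep_sea_patches
        )

    res = run(lulc, coastline, config)

    write_coastline(coastline, out_dir / "coastline.geojson", lulc.crs_descriptor)
    write_outputs(lulc, result_table(res), out_dir / "result.geojson")
    res.crosstab.to_csv(out_dir / "crosstab.csv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return res
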