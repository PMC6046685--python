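"""Synthetic coastal-landscape fixtures.

Real land-cover inputs are large regional exports; for testing and for the
worked examples the pipeline instead runs on generated grids: ``rows``
patch rows inland by ``cols`` patches alongshore, square cells of
``cell_size`` metres, the seaward grid edge serving as the coastline.  On a
full grid under rook contiguity, a patch's band level equals its row index
plus one — a closed-form ground truth for every stage.

Class codes are drawn per cell from ``class_weights`` with a seeded
generator (NumPy PCG64, fixed so fixtures are stable across releases), and
deterministic *motifs* are then stamped on top:

* ``corridor(col, depth)`` — a natural chain down column *col* through
  bands 1..depth (a transversally connected mosaic).
* ``hinge(col, band)`` — a three-column natural block whose only link at
  the stated band is the centre cell: artificialize it and everything
  deeper is stranded.
* ``barrier(col, depth)`` — a natural chain in bands 2..depth behind an
  artificial waterfront cell: the restorable-barrier situation.

Motifs that overlap with conflicting codes raise a generation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Polygon

from .errors import GenerationError
from .geoio import Coastline, LandCoverMap, Patch

#: codes used when stamping motifs
NATURAL_CODE = "311"
ARTIFICIAL_CODE = "112"

DEFAULT_CLASS_WEIGHTS = {
    # broadleaf/conifer/mixed forest, scrub, beaches — the natural mixture
    "311": 0.18,
    "312": 0.12,
    "313": 0.10,
    "324": 0.12,
    "331": 0.08,
    # arable / permanent crops / pasture
    "211": 0.10,
    "222": 0.08,
    "231": 0.07,
    # urban fabric / industrial / road-rail
    "112": 0.08,
    "121": 0.04,
    "122": 0.03,
}


@dataclass(frozen=True)
class Corridor:
    col: int
    depth: int


@dataclass(frozen=True)
class Hinge:
    col: int
    band: int
    depth: int | None = None  # natural block depth; defaults to band + 2


@dataclass(frozen=True)
class Barrier:
    col: int
    depth: int


Motif = Corridor | Hinge | Barrier


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic coastal strip."""

    rows: int = 10
    cols: int = 20
    cell_size: float = 100.0
    class_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    seed: int = 0
    motifs: tuple[Motif, ...] = ()

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise GenerationError("rows and cols must be >= 1")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"class_weights sum to {total}, expected 1")


def _motif_cells(motif: Motif, spec: SyntheticSpec) -> dict[tuple[int, int], str]:
    """Cells (row, col) -> code stamped by one motif; row 0 is the waterfront."""
    cells: dict[tuple[int, int], str] = {}
    if isinstance(motif, Corridor):
        if not (0 <= motif.col < spec.cols and 1 <= motif.depth <= spec.rows):
            raise GenerationError(f"corridor {motif} does not fit a {spec.rows}x{spec.cols} grid")
        for r in range(motif.depth):
            cells[(r, motif.col)] = NATURAL_CODE
    elif isinstance(motif, Hinge):
        depth = motif.depth if motif.depth is not None else motif.band + 2
        if not (1 <= motif.col < spec.cols - 1 and 1 <= motif.band <= depth <= spec.rows):
            raise GenerationError(f"hinge {motif} does not fit a {spec.rows}x{spec.cols} grid")
        for r in range(depth):
            for c in (motif.col - 1, motif.col, motif.col + 1):
                cells[(r, c)] = NATURAL_CODE
        hinge_row = motif.band - 1
        cells[(hinge_row, motif.col - 1)] = ARTIFICIAL_CODE
        cells[(hinge_row, motif.col + 1)] = ARTIFICIAL_CODE
    elif isinstance(motif, Barrier):
        if not (0 <= motif.col < spec.cols and 2 <= motif.depth <= spec.rows):
            raise GenerationError(f"barrier {motif} does not fit a {spec.rows}x{spec.cols} grid")
        cells[(0, motif.col)] = ARTIFICIAL_CODE
        for r in range(1, motif.depth):
            cells[(r, motif.col)] = NATURAL_CODE
    else:  # pragma: no cover - guarded by the Motif union
        raise GenerationError(f"unknown motif {motif!r}")
    return cells


def generate(spec: SyntheticSpec) -> tuple[LandCoverMap, Coastline]:
    """Generate a grid fixture: random codes, then motifs, then the coastline.

    The same spec (including seed) always yields byte-identical layers.
    Patch ids are ``r<row>c<col>``; the coastline is the seaward grid edge
    (y = 0), with rows extending inland to negative y.
    """
    rng = np.random.default_rng(spec.seed)
    codes = list(spec.class_weights)
    probs = np.array([spec.class_weights[c] for c in codes])
    draw = rng.choice(len(codes), size=(spec.rows, spec.cols), p=probs)
    grid = [[codes[draw[r, c]] for c in range(spec.cols)] for r in range(spec.rows)]

    stamped: dict[tuple[int, int], tuple[str, Motif]] = {}
    for motif in spec.motifs:
        for cell, code in _motif_cells(motif, spec).items():
            if cell in stamped and stamped[cell][0] != code:
                raise GenerationError(
                    f"motif collision at cell {cell}: {stamped[cell][1]} vs {motif}"
                )
            stamped[cell] = (code, motif)
            grid[cell[0]][cell[1]] = code

    s = spec.cell_size
    patches = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            cell = Polygon(
                [(c * s, -r * s), ((c + 1) * s, -r * s), ((c + 1) * s, -(r + 1) * s), (c * s, -(r + 1) * s)]
            )
            patches.append(Patch(f"r{r}c{c}", cell, grid[r][c]))
    lulc = LandCoverMap(patches, crs_descriptor="urn:coastband:synthetic-planar", code_field="CODE_18")
    coast = Coastline(LineString([(0.0, 0.0), (spec.cols * s, 0.0)]))
    return lulc, coast


def worked_example_chain(depth_from: int = 1, depth_to: int = 8, B: int = 10) -> tuple[LandCoverMap, Coastline]:
    """Minimal fixture: a single natural chain occupying bands 1..depth_to.

    One column of natural cells perpendicular to the coast — the textbook
    configuration for continuity depth: every patch in the chain has
    TCD = depth_to, in particular the patch at band *depth_from*.
    """
    if not 1 <= depth_from <= depth_to <= B:
        raise GenerationError(f"need 1 <= depth_from <= depth_to <= {B}")
    spec = SyntheticSpec(
        rows=depth_to,
        cols=1,
        class_weights={NATURAL_CODE: 1.0},
        seed=0,
    )
    return generate(spec)
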