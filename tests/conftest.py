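"""Shared fixtures: small hand-built maps and randomized grid landscapes."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from coastband.geoio import Coastline, LandCoverMap, Patch
from coastband.synthgen import SyntheticSpec, generate


def square(x0, y0, size=1.0):
    return Polygon([(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)])


def make_map(patches, crs="urn:test:planar"):
    return LandCoverMap(list(patches), crs_descriptor=crs)


@pytest.fixture
def coast_line():
    """Straight coastline along y=0 for hand-built maps sitting in y<0."""
    return Coastline(LineString([(-100, 0), (100, 0)]))


def random_landscape(rng: np.random.Generator, max_rows=10, max_cols=10, hole_frac=0.25):
    """Random grid landscape with holes: varied topology, <=100 patches.

    Cells are deleted at random, which fragments the grid and produces
    disconnected components, dead ends and patches unreachable from the
    coast — the cases the oracles must agree on.
    """
    rows = int(rng.integers(2, max_rows + 1))
    cols = int(rng.integers(2, max_cols + 1))
    weights = {"311": 0.35, "313": 0.15, "211": 0.2, "112": 0.2, "331": 0.1}
    spec = SyntheticSpec(rows=rows, cols=cols, seed=int(rng.integers(2**31)), class_weights=weights)
    lulc, coast = generate(spec)
    keep = [p for p in lulc.patches if rng.random() > hole_frac]
    if not keep:
        keep = lulc.patches[:1]
    holed = LandCoverMap(keep, crs_descriptor=lulc.crs_descriptor, code_field=lulc.code_field)
    return holed, coast
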