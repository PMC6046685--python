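"""Cross-tabulation, hinge detection and barrier detection."""

import numpy as np
import pytest

from coastband.adjacency import build_adjacency
from coastband.banding import assign_bands
from coastband.connectivity import NatureScheme, assign_tcd, extract_tcnlm
from coastband.geoio import LandCoverMap, Patch
from coastband.interpret import cross_tabulate, find_barriers, find_endangered
from coastband.synthgen import Barrier, Hinge, SyntheticSpec, generate, worked_example_chain
from conftest import make_map, random_landscape, square


def _stages(lulc, coast, scheme=NatureScheme(), B=10):
    graph = build_adjacency(lulc, coast)
    bands = assign_bands(graph, B)
    mosaics = extract_tcnlm(bands, graph, lulc, scheme)
    tcd = assign_tcd(mosaics, bands, graph)
    return graph, bands, mosaics, tcd


class TestCrossTab:
    def test_empty_mosaic_gives_all_zero_matrix(self, coast_line):
        lulc = make_map([Patch("a", square(0, -1), "112")])
        _, bands, _, tcd = _stages(lulc, coast_line)
        tab = cross_tabulate(bands, tcd)
        assert tab.values.sum() == 0
        assert tab.shape == (10, 10)

    def test_single_chain_fills_one_column(self):
        lulc, coast = worked_example_chain(1, 8)
        _, bands, _, tcd = _stages(lulc, coast)
        tab = cross_tabulate(bands, tcd)
        assert (tab[8].loc[1:8] == 1).all()
        assert tab.values.sum() == 8
        assert (tab.drop(columns=8).values == 0).all()

    def test_total_is_member_count_and_lower_triangle_zero(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            lulc, coast = random_landscape(rng)
            _, bands, mosaics, tcd = _stages(lulc, coast)
            tab = cross_tabulate(bands, tcd, lulc)
            assert tab.values.sum() == len(mosaics.members)
            for b in tab.index:
                for t in tab.columns:
                    if t < b:
                        assert tab.loc[b, t] == 0
            # per-cell areas accompany the counts
            assert tab.attrs["area_m2"].values.sum() == pytest.approx(
                sum(lulc[p].area for p in mosaics.members)
            )


class TestEndangered:
    @pytest.mark.filterwarnings("ignore:band_max")
    def test_middle_of_three_chain_flagged_with_dependents(self, coast_line):
        lulc = make_map([Patch(f"p{r}", square(0, -(r + 1)), "311") for r in range(3)])
        graph, bands, mosaics, tcd = _stages(lulc, coast_line)
        flagged = find_endangered(mosaics, bands, graph, tcd, lulc, band_max=4, tcd_min=3)
        by_id = {e.id: e for e in flagged}
        assert by_id["p1"].dependent_patch_ids == {"p2"}
        assert by_id["p1"].unique_in_band_within_mosaic
        assert all(bands[d] > e.band for e in flagged for d in e.dependent_patch_ids)

    def test_sole_link_to_deep_corridor_flagged(self, coast_line):
        """One band-2 patch alone links the deep corridor coastward: a hinge."""
        from shapely.geometry import box

        patches = [
            # two independent band-1 frontage patches
            Patch("a1", box(0, -1, 1, 0), "311"),
            Patch("a2", box(1, -1, 2, 0), "311"),
            # single band-2 link spanning both columns
            Patch("link", box(0, -2, 2, -1), "311"),
            # deep corridor hanging off the link
            Patch("b3", box(0, -3, 1, -2), "311"),
            Patch("b4", box(0, -4, 1, -3), "311"),
            Patch("b5", box(0, -5, 1, -4), "311"),
        ]
        lulc = make_map(patches)
        graph, bands, mosaics, tcd = _stages(lulc, coast_line)
        assert bands["link"] == 2 and bands["b3"] == 3
        # candidates limited to bands 1-2: a1/a2 are redundant, link is not
        flagged = find_endangered(mosaics, bands, graph, tcd, lulc, band_max=2, tcd_min=3)
        assert {e.id for e in flagged} == {"link"}
        assert flagged[0].dependent_patch_ids == {"b3", "b4", "b5"}

    def test_redundant_links_not_flagged(self, coast_line):
        """Two parallel band-2 links to the same deep corridor: neither is a hinge."""
        from shapely.geometry import box

        patches = [
            Patch("front", box(0, -1, 2, 0), "311"),
            Patch("l0", box(0, -2, 1, -1), "311"),
            Patch("l1", box(1, -2, 2, -1), "311"),
            Patch("deep3", box(0, -3, 2, -2), "311"),
            Patch("deep4", box(0, -4, 2, -3), "311"),
        ]
        lulc = make_map(patches)
        graph, bands, mosaics, tcd = _stages(lulc, coast_line)
        flagged = find_endangered(mosaics, bands, graph, tcd, lulc, band_max=2, tcd_min=3)
        assert {e.id for e in flagged} & {"l0", "l1"} == set()
        # the two links have empty dependent sets; the sole frontage patch is
        # itself a hinge for everything behind it
        assert {e.id for e in flagged} == {"front"}

    @pytest.mark.filterwarnings("ignore:band_max")
    def test_dependent_sets_verified_by_recomputation(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(15):
            lulc, coast = random_landscape(rng)
            graph, bands, mosaics, tcd = _stages(lulc, coast)
            flagged = find_endangered(mosaics, bands, graph, tcd, lulc, band_max=9, tcd_min=2)
            for e in flagged:
                # full Stage-2 recomputation with the candidate artificialized
                altered = LandCoverMap(
                    [p if p.id != e.id else Patch(p.id, p.geometry, "112") for p in lulc.patches],
                    crs_descriptor=lulc.crs_descriptor,
                )
                g2 = build_adjacency(altered, coast)
                b2 = assign_bands(g2, 10)
                m2 = extract_tcnlm(b2, g2, altered)
                assert mosaics.members - m2.members - {e.id} == e.dependent_patch_ids
                checked += 1
        assert checked > 0

    def test_vacuous_threshold_warns(self, coast_line):
        lulc = make_map([Patch("a", square(0, -1), "311")])
        graph, bands, mosaics, tcd = _stages(lulc, coast_line)
        with pytest.warns(UserWarning, match="vacuous"):
            find_endangered(mosaics, bands, graph, tcd, lulc, band_max=5, tcd_min=3)


class TestBarriers:
    def test_artificial_front_of_natural_chain_flagged_with_depth(self):
        spec = SyntheticSpec(rows=6, cols=3, class_weights={"211": 1.0},
                             motifs=(Barrier(col=1, depth=6),), seed=0)
        lulc, coast = generate(spec)
        graph, bands, mosaics, _ = _stages(lulc, coast)
        flagged = find_barriers(lulc, bands, graph)
        assert [b.id for b in flagged] == ["r0c1"]
        assert flagged[0].unlocked_depth == 6
        assert flagged[0].unlocked_mosaic_member_ids == {f"r{r}c1" for r in range(1, 6)}

    def test_artificial_patch_with_artificial_hinterland_not_flagged(self, coast_line):
        lulc = make_map([Patch("a", square(0, -1), "112"), Patch("b", square(0, -2), "121")])
        graph, bands, _, _ = _stages(lulc, coast_line)
        assert find_barriers(lulc, bands, graph) == []

    def test_natural_band1_never_flagged(self):
        rng = np.random.default_rng(43)
        from coastband.connectivity import classify_code

        for _ in range(10):
            lulc, coast = random_landscape(rng)
            graph, bands, _, _ = _stages(lulc, coast)
            for b in find_barriers(lulc, bands, graph):
                assert classify_code(lulc[b.id].clc_code) == "artificial"
                assert bands[b.id] == 1
                assert all(bands[p] >= 2 for p in b.unlocked_mosaic_member_ids)

    def test_exclude_already_connected_drops_redundant_barriers(self, coast_line):
        """A band-2 patch reachable both through the artificial front and
        through a natural band-1 neighbour is no longer grounds for a flag."""
        from shapely.geometry import box

        lulc = make_map([
            Patch("art", box(0, -1, 1, 0), "112"),
            Patch("nat1", box(1, -1, 2, 0), "311"),
            Patch("deep", box(0, -2, 2, -1), "311"),  # touches both fronts
        ])
        graph, bands, _, _ = _stages(lulc, coast_line)
        default = find_barriers(lulc, bands, graph)
        strict = find_barriers(lulc, bands, graph, exclude_already_connected=True)
        assert {b.id for b in default} == {"art"}
        assert strict == []

    def test_flags_invariant_under_id_permutation(self):
        rng = np.random.default_rng(44)
        lulc, coast = random_landscape(rng)
        graph, bands, _, _ = _stages(lulc, coast)
        base = {b.id for b in find_barriers(lulc, bands, graph)}
        renamed = LandCoverMap(
            [Patch("z" + p.id, p.geometry, p.clc_code) for p in reversed(lulc.patches)],
            crs_descriptor=lulc.crs_descriptor,
        )
        g2 = build_adjacency(renamed, coast)
        b2 = assign_bands(g2, 10)
        assert {b.id for b in find_barriers(renamed, b2, g2)} == {"z" + i for i in base}
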