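"""Geometry and raster primitives: majority rasterization, overlay union,
centroids, canopy area accounting."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from atollcarbon.spatial_core import (
    BLANK,
    GRASSLAND,
    RUNWAY,
    WATER,
    AttributedPolygon,
    CategoricalRaster,
    GridSpec,
    canopy_area,
    crown_centroid,
    geometric_union,
    rasterize_majority,
    vectorize,
)


def grid3() -> GridSpec:
    return GridSpec(origin=(0.0, 3.0), cell_size=1.0, width=3, height=3)


class TestRasterizeMajority:
    def test_single_full_cover_polygon_labels_all_cells(self):
        polys = [AttributedPolygon(box(0, 0, 3, 3), community="A")]
        r = rasterize_majority(polys, grid3(), "community")
        assert all(r.legend[int(c)] == "A" for c in np.unique(r.codes))

    def test_majority_wins_in_overlap(self):
        # A covers the left 2 columns, B the right 1.5: the contested middle
        # column is fully covered by A but only half-covered by B
        polys = [
            AttributedPolygon(box(0, 0, 2, 3), community="A"),
            AttributedPolygon(box(1.5, 0, 3, 3), community="B"),
        ]
        r = rasterize_majority(polys, grid3(), "community")
        labels = np.vectorize(r.legend.get)(r.codes)
        assert (labels[:, 0] == "A").all()
        assert (labels[:, 1] == "A").all()
        assert (labels[:, 2] == "B").all()

    def test_uncovered_cells_blank(self):
        polys = [AttributedPolygon(box(0, 2, 1, 3), community="A")]
        r = rasterize_majority(polys, grid3(), "community")
        assert r.codes[0, 0] != BLANK
        assert r.codes[2, 2] == BLANK

    def test_tie_breaks_to_lowest_legend_code(self):
        # exact 50/50 split of the single cell; "A" sorts before "B" so it
        # receives the lower code and wins
        g = GridSpec(origin=(0.0, 1.0), cell_size=1.0, width=1, height=1)
        polys = [
            AttributedPolygon(box(0.5, 0, 1, 1), community="B"),
            AttributedPolygon(box(0, 0, 0.5, 1), community="A"),
        ]
        r = rasterize_majority(polys, g, "community")
        assert r.legend[int(r.codes[0, 0])] == "A"

    def test_empty_list_and_bad_attribute_error(self):
        with pytest.raises(ValueError):
            rasterize_majority([], grid3(), "community")
        with pytest.raises(ValueError):
            rasterize_majority(
                [AttributedPolygon(box(0, 0, 1, 1), community="A")], grid3(), "height"
            )

    def test_roundtrip_on_grid_snapped_polygons(self):
        polys = [
            AttributedPolygon(box(0, 0, 2, 3), community="A"),
            AttributedPolygon(box(2, 0, 3, 3), community="B"),
        ]
        r = rasterize_majority(polys, grid3(), "community")
        back = rasterize_majority(vectorize(r), grid3(), "community")
        assert (back.codes == r.codes).all()


class TestGeometricUnion:
    def test_disjoint_squares_keep_single_labels(self):
        a = AttributedPolygon(box(0, 0, 1, 1), community="A")
        b = AttributedPolygon(box(2, 0, 3, 1), species="B")
        pieces = geometric_union([a], [b])
        labels = sorted((p.community, p.species) for p in pieces)
        assert labels == [("", "B"), ("A", "")]

    def test_identical_squares_merge_labels(self):
        a = AttributedPolygon(box(0, 0, 1, 1), community="A")
        b = AttributedPolygon(box(0, 0, 1, 1), species="B")
        pieces = geometric_union([a], [b])
        assert len(pieces) == 1
        assert (pieces[0].community, pieces[0].species) == ("A", "B")

    def test_partial_overlap_three_pieces(self):
        a = AttributedPolygon(box(0, 0, 1, 1), community="A")
        b = AttributedPolygon(box(0.5, 0, 1.5, 1), species="B")
        pieces = geometric_union([a], [b])
        areas = {
            (p.community, p.species): pytest.approx(p.geometry.area, abs=1e-9)
            for p in pieces
        }
        assert areas == {("A", ""): 0.5, ("A", "B"): 0.5, ("", "B"): 0.5}

    def test_area_conservation(self):
        a = [
            AttributedPolygon(box(0, 0, 4, 2), community="A"),
            AttributedPolygon(box(4, 0, 6, 2), community="C"),
        ]
        b = [AttributedPolygon(Polygon([(1, 0), (5, 0), (5, 2), (1, 1)]), species="B")]
        pieces = geometric_union(a, b)
        import shapely

        expect = shapely.union_all(
            [p.geometry for p in a] + [p.geometry for p in b]
        ).area
        assert sum(p.geometry.area for p in pieces) == pytest.approx(expect, rel=1e-3)


class TestCrownCentroid:
    @pytest.mark.parametrize(
        "coords, expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], (0.5, 0.5)),
            ([(0, 0), (1, 0), (0, 1)], (1 / 3, 1 / 3)),
        ],
    )
    def test_known_centroids(self, coords, expected):
        c = crown_centroid(Polygon(coords))
        assert (c.x, c.y) == pytest.approx(expected)

    def test_l_shape_matches_decomposition(self):
        # two unit squares: centroid is the mean of their centroids
        l_shape = Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])
        c = crown_centroid(l_shape)
        cx = (0.5 * 1 + 1.5 * 1) / 2  # squares at (0,0)-(1,2) split: use boxes
        sq1, sq2 = box(0, 0, 1, 2), box(1, 0, 2, 1)
        ex = (sq1.centroid.x * 2 + sq2.centroid.x * 1) / 3
        ey = (sq1.centroid.y * 2 + sq2.centroid.y * 1) / 3
        assert (c.x, c.y) == pytest.approx((ex, ey))

    def test_zero_area_errors(self):
        with pytest.raises(ValueError):
            crown_centroid(Polygon())


class TestCanopyArea:
    def _raster(self, codes):
        g = GridSpec(origin=(0.0, codes.shape[0]), cell_size=1.0,
                     width=codes.shape[1], height=codes.shape[0])
        legend = {0: "", 1: "water", 2: "unknown", 3: "runway", 4: "bare_ground",
                  5: "grassland", 10: "canopy"}
        return CategoricalRaster(grid=g, codes=codes, legend=legend)

    def test_all_runway_zero(self):
        r = self._raster(np.full((10, 10), RUNWAY))
        assert canopy_area(r) == 0.0

    def test_unit_conversion_10000_cells_is_one_ha(self):
        r = self._raster(np.full((100, 100), 10))
        assert canopy_area(r) == pytest.approx(1.0)

    def test_mixed_raster_matches_histogram(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 1, 2, 3, 4, 5, 10], size=(50, 40))
        r = self._raster(codes)
        included = (codes == 10).sum()
        assert canopy_area(r) == pytest.approx(included * 1e-4)
        # partition: canopy + excluded + water/blank = total grid area
        total = codes.size * 1e-4
        excl = np.isin(codes, [2, 3, 4, 5]).sum() * 1e-4
        waterblank = np.isin(codes, [0, 1]).sum() * 1e-4
        assert canopy_area(r) + excl + waterblank == pytest.approx(total)


def test_gridspec_validation():
    with pytest.raises(ValueError):
        GridSpec(origin=(0, 0), cell_size=0.0, width=1, height=1)
    with pytest.raises(ValueError):
        GridSpec(origin=(0, 0), cell_size=1.0, width=0, height=1)
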