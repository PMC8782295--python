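"""Transformation scenario: survivor mix, reclassification, crown reassignment."""

import numpy as np
import pytest
from shapely.geometry import Point, box

from atollcarbon.aboveground_carbon import TreeRecord
from atollcarbon.scenario import (
    C_NUCIFERA,
    H_FOERTHERIANUM,
    P_GRANDIS,
    TransformationPlan,
    expected_survivor_mix,
    percent_change,
    reassign_crowns,
    reclassify_communities,
    scenario_summary,
)
from atollcarbon.spatial_core import CategoricalRaster, GridSpec


class TestSurvivorMix:
    def test_half_survival_cancels_double_planting(self):
        mix = expected_survivor_mix({"H": 2, "P": 1}, {"H": 0.5, "P": 1.0})
        assert mix == {"H": 0.5, "P": 0.5}

    def test_published_survival_near_half(self):
        mix = expected_survivor_mix({"H": 2, "P": 1}, {"H": 0.46, "P": 1.0})
        assert mix["H"] == pytest.approx(0.92 / 1.92, abs=1e-4)  # 0.479
        assert mix["P"] == pytest.approx(1.0 / 1.92, abs=1e-4)   # 0.521

    def test_equal_everything_is_even_split(self):
        assert expected_survivor_mix({"H": 1, "P": 1}, {"H": 1, "P": 1}) == {
            "H": 0.5, "P": 0.5,
        }

    def test_no_survivors_errors(self):
        with pytest.raises(ValueError):
            expected_survivor_mix({"H": 0}, {"H": 1.0})


def _community_raster(n=20):
    g = GridSpec(origin=(0.0, float(n)), cell_size=1.0, width=n, height=n)
    legend = {0: "", 1: "water", 2: "unknown", 3: "runway", 4: "bare_ground",
              5: "grassland", 10: "C. nucifera", 11: "P. grandis",
              12: "P. grandis/H. foertherianum"}
    codes = np.full((n, n), 10)
    codes[:, : n // 2] = 11  # left half native
    return CategoricalRaster(grid=g, codes=codes, legend=legend)


class TestReclassify:
    def test_no_overlap_is_identity(self):
        r = _community_raster()
        plan = TransformationPlan(polygons=[box(100, 100, 110, 110)])
        out = reclassify_communities(r, plan)
        assert (out.codes == r.codes).all()

    def test_full_cover_removes_all_palm_cells(self):
        r = _community_raster()
        plan = TransformationPlan(polygons=[box(-1, -1, 21, 21)])
        out = reclassify_communities(r, plan)
        assert (out.codes == 10).sum() == 0
        assert (out.codes == 12).sum() == (r.codes == 10).sum()

    def test_partial_overlap_changes_exactly_covered_cells(self):
        r = _community_raster()
        plan = TransformationPlan(polygons=[box(10, 0, 20, 10)])  # palm quadrant
        out = reclassify_communities(r, plan)
        changed = (out.codes != r.codes).sum()
        assert changed == 100  # 10x10 palm cells inside the polygon

    def test_cell_count_and_nontarget_cells_conserved(self):
        r = _community_raster()
        plan = TransformationPlan(polygons=[box(10, 0, 20, 10)])
        out = reclassify_communities(r, plan)
        assert out.codes.size == r.codes.size
        native = r.codes == 11
        assert (out.codes[native] == r.codes[native]).all()

    def test_missing_replacement_class_errors(self):
        r = _community_raster()
        del r.legend[12]
        plan = TransformationPlan(polygons=[box(0, 0, 5, 5)])
        with pytest.raises(ValueError):
            reclassify_communities(r, plan)


def _palm_crowns(n, inside=True):
    x = 5.0 if inside else 100.0
    return [
        TreeRecord(species=C_NUCIFERA, centroid=Point(x, 5.0), height=18.0,
                   diameter=30.0, bwd=0.5)
        for _ in range(n)
    ]


_HEIGHTS = {P_GRANDIS: 12.0, H_FOERTHERIANUM: 6.0}
_DIAMS = {P_GRANDIS: 35.0, H_FOERTHERIANUM: 15.0}
_BWD = {P_GRANDIS: 0.23, H_FOERTHERIANUM: 0.31}


class TestReassignCrowns:
    def _plan(self, seed=0):
        return TransformationPlan(polygons=[box(0, 0, 10, 10)], seed=seed)

    def test_no_targets_is_identity(self):
        crowns = _palm_crowns(5, inside=False)
        out = reassign_crowns(crowns, self._plan(), _HEIGHTS, _DIAMS, _BWD)
        assert all(a is b for a, b in zip(crowns, out))

    def test_crown_count_conserved_and_split_binomial(self):
        crowns = _palm_crowns(10_000)
        out = reassign_crowns(crowns, self._plan(seed=3), _HEIGHTS, _DIAMS, _BWD)
        assert len(out) == 10_000
        species = [t.species for t in out]
        assert C_NUCIFERA not in species
        n_pg = species.count(P_GRANDIS)
        props = self._plan().replacement_proportions
        expect = props[P_GRANDIS] * 10_000
        sd = np.sqrt(10_000 * props[P_GRANDIS] * (1 - props[P_GRANDIS]))
        assert abs(n_pg - expect) <= 3 * sd

    def test_replanted_trees_get_species_means(self):
        out = reassign_crowns(_palm_crowns(50), self._plan(), _HEIGHTS, _DIAMS, _BWD)
        t = out[0]
        assert t.height == _HEIGHTS[t.species]
        assert t.diameter == _DIAMS[t.species]
        assert t.height_source == "species_mean"

    def test_same_seed_identical_assignment(self):
        a = reassign_crowns(_palm_crowns(200), self._plan(seed=9), _HEIGHTS, _DIAMS, _BWD)
        b = reassign_crowns(_palm_crowns(200), self._plan(seed=9), _HEIGHTS, _DIAMS, _BWD)
        assert [t.species for t in a] == [t.species for t in b]

    def test_exact_split_mode(self):
        plan = TransformationPlan(
            polygons=[box(0, 0, 10, 10)],
            survival={H_FOERTHERIANUM: 0.5, P_GRANDIS: 1.0},
            exact_split=True,
        )
        out = reassign_crowns(_palm_crowns(100), plan, _HEIGHTS, _DIAMS, _BWD)
        species = [t.species for t in out]
        assert species.count(P_GRANDIS) == 50


class TestPercentChange:
    @pytest.mark.parametrize(
        "baseline, future, expected",
        [
            (692.6, 433.3, -37.4),
            (11872.3, 13590.8, 14.5),
            (5.0, 5.0, 0.0),
        ],
    )
    def test_published_and_trivial_cells(self, baseline, future, expected):
        assert percent_change(baseline, future) == expected

    def test_zero_baseline_flagged(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)


class TestScenarioSummary:
    def test_published_components_reproduce_totals(self):
        s = scenario_summary(692.6, 11872.3, 433.3, 13590.8, canopy_area_ha=161.8)
        assert s.baseline["total"] == pytest.approx(12564.9)
        assert s.future["total"] == pytest.approx(14024.1)
        assert s.pct_change == {"aboveground": -37.4, "soil": 14.5, "total": 11.6}

    def test_identical_scenes_all_zero_change(self):
        s = scenario_summary(100.0, 200.0, 100.0, 200.0, canopy_area_ha=10.0)
        assert set(s.pct_change.values()) == {0.0}

    def test_mismatched_canopy_areas_error(self):
        with pytest.raises(ValueError):
            scenario_summary(1, 2, 1, 2, canopy_area_ha=10.0, future_canopy_area_ha=12.0)
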