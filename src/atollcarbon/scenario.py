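"""Forest-transformation scenario: project the future scene and compare budgets.

Inside the transformation polygons (planned to cover ~95% of emergent land)
all *C. nucifera* is removed and *H. foertherianum* / *P. grandis* are
planted at a 2:1 ratio.  With *H. foertherianum* seedling survival at 46%
the mature forest ends up near a 50:50 species split, so community cells are
reclassified to the mixed *P. grandis/H. foertherianum* class and crown
points are randomly reassigned between the two natives.  Replanted trees get
study-wide species mean heights and quadratic-mean diameters ("maturity at
15 years" accounting — no growth curve in between).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .aboveground_carbon import TreeRecord
from .spatial_core import CategoricalRaster

C_NUCIFERA = "Cocos nucifera"
P_GRANDIS = "Pisonia grandis"
H_FOERTHERIANUM = "Heliotropium foertherianum"

#: community-class relabelling applied inside transformation polygons;
#: interpretive mapping for the mixed C. nucifera communities
DEFAULT_COMMUNITY_MAP = {
    "C. nucifera": "P. grandis/H. foertherianum",
    "C. nucifera/H. foertherianum": "P. grandis/H. foertherianum",
}


@dataclass
class TransformationPlan:
    polygons: list[Polygon]
    remove_species: str = C_NUCIFERA
    planting_ratio: dict[str, float] = field(
        default_factory=lambda: {H_FOERTHERIANUM: 2.0, P_GRANDIS: 1.0}
    )
    survival: dict[str, float] = field(
        default_factory=lambda: {H_FOERTHERIANUM: 0.46, P_GRANDIS: 1.0}
    )
    maturity_years: int = 15
    community_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMMUNITY_MAP)
    )
    exact_split: bool = False  # exact half-split instead of Bernoulli draws
    seed: int = 0

    def __post_init__(self) -> None:
        for sp, s in self.survival.items():
            if not 0 < s <= 1:
                raise ValueError(f"survival for {sp} must lie in (0, 1]")

    @property
    def replacement_proportions(self) -> dict[str, float]:
        return expected_survivor_mix(self.planting_ratio, self.survival)


def expected_survivor_mix(
    planting_ratio: dict[str, float], survival: dict[str, float]
) -> dict[str, float]:
    """Mature-forest species proportions: planted count x survival, normalized."""
    weights = {sp: planting_ratio[sp] * survival.get(sp, 1.0) for sp in planting_ratio}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no survivors under this plan")
    return {sp: w / total for sp, w in weights.items()}


def _inside_mask(raster: CategoricalRaster, polygons: list[Polygon]) -> np.ndarray:
    xs, ys = raster.grid.cell_centers()
    union = shapely.union_all(polygons)
    return shapely.contains_xy(union, xs.ravel(), ys.ravel()).reshape(xs.shape)


def reclassify_communities(
    raster: CategoricalRaster, plan: TransformationPlan
) -> CategoricalRaster:
    """Relabel community cells inside the plan polygons per the class map.

    Only mapped classes change; cell count and all other cells are untouched.
    """
    label_to_code = {v: k for k, v in raster.legend.items()}
    for target in set(plan.community_map.values()):
        if target not in label_to_code:
            raise ValueError(f"replacement class {target!r} missing from legend")
    inside = _inside_mask(raster, plan.polygons)
    codes = raster.codes.copy()
    for src, dst in plan.community_map.items():
        if src not in label_to_code:
            continue
        sel = inside & (raster.codes == label_to_code[src])
        codes[sel] = label_to_code[dst]
    return CategoricalRaster(grid=raster.grid, codes=codes, legend=dict(raster.legend))


def reassign_crowns(
    crowns: list[TreeRecord],
    plan: TransformationPlan,
    species_mean_heights: dict[str, float],
    species_diameters: dict[str, float],
    bwd_means: dict[str, float],
) -> list[TreeRecord]:
    """Replace removed-species crowns inside the plan polygons with natives.

    Each targeted crown independently becomes one of the replacement species
    with the plan's survivor proportions (or an exact half-split when
    ``plan.exact_split``); replanted trees carry study-wide species mean
    height, quadratic-mean diameter and mean wood density.  Other crowns are
    returned unchanged (same objects).  Deterministic for a fixed plan seed.
    """
    props = plan.replacement_proportions
    species_list = sorted(props)
    for sp in species_list:
        if sp not in species_mean_heights:
            raise ValueError(f"no mean height for replacement species {sp!r}")
    union = shapely.union_all(plan.polygons)
    targets = [
        i
        for i, t in enumerate(crowns)
        if t.species == plan.remove_species and union.contains(t.centroid)
    ]
    rng = np.random.default_rng(plan.seed)
    if plan.exact_split:
        n = len(targets)
        counts = {sp: int(round(props[sp] * n)) for sp in species_list}
        counts[species_list[-1]] = n - sum(counts[sp] for sp in species_list[:-1])
        pool = [sp for sp in species_list for _ in range(counts[sp])]
        rng.shuffle(pool)
        assigned = pool
    else:
        assigned = rng.choice(
            species_list, size=len(targets), p=[props[sp] for sp in species_list]
        )
    out = list(crowns)
    for idx, new_sp in zip(targets, assigned):
        old = crowns[idx]
        out[idx] = TreeRecord(
            species=str(new_sp),
            geometry=old.geometry,
            centroid=old.centroid,
            height=species_mean_heights[new_sp],
            height_source="species_mean",
            diameter=species_diameters[new_sp],
            bwd=bwd_means[new_sp],
        )
    return out


def reassign_species_raster(
    raster: CategoricalRaster, plan: TransformationPlan
) -> CategoricalRaster:
    """Cell-level analogue of crown reassignment for the species raster.

    Removed-species cells inside the plan polygons are randomly relabelled to
    the replacement species with the survivor proportions; uses a substream
    of the plan seed so raster and crown draws stay independent.
    """
    label_to_code = {v: k for k, v in raster.legend.items()}
    props = plan.replacement_proportions
    species_list = sorted(props)
    for sp in species_list:
        if sp not in label_to_code:
            raise ValueError(f"replacement species {sp!r} missing from legend")
    if plan.remove_species not in label_to_code:
        return CategoricalRaster(
            grid=raster.grid, codes=raster.codes.copy(), legend=dict(raster.legend)
        )
    inside = _inside_mask(raster, plan.polygons)
    sel = inside & (raster.codes == label_to_code[plan.remove_species])
    rng = np.random.default_rng([7, plan.seed])
    picks = rng.choice(
        [label_to_code[sp] for sp in species_list],
        size=int(sel.sum()),
        p=[props[sp] for sp in species_list],
    )
    codes = raster.codes.copy()
    codes[sel] = picks
    return CategoricalRaster(grid=raster.grid, codes=codes, legend=dict(raster.legend))


def percent_change(baseline: float, future: float) -> float:
    """(future - baseline) / baseline x 100, to one decimal."""
    if baseline == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return round((future - baseline) / baseline * 100.0, 1)


@dataclass
class ScenarioSummary:
    """Baseline vs. future totals (Mg C), densities (Mg C ha^-1), % changes."""

    canopy_area_ha: float
    baseline: dict[str, float]
    future: dict[str, float]
    pct_change: dict[str, float]


def scenario_summary(
    baseline_aboveground: float,
    baseline_soil: float,
    future_aboveground: float,
    future_soil: float,
    canopy_area_ha: float,
    future_canopy_area_ha: float | None = None,
) -> ScenarioSummary:
    """Assemble the pre/post carbon summary with internal additivity checks.

    Transformation changes vegetation identity, not land cover, so the
    canopy area must agree between scenes.
    """
    if future_canopy_area_ha is not None and not np.isclose(
        canopy_area_ha, future_canopy_area_ha, rtol=1e-6
    ):
        raise ValueError("canopy areas differ between baseline and future scenes")
    base_total = baseline_aboveground + baseline_soil
    fut_total = future_aboveground + future_soil
    baseline = {
        "aboveground": baseline_aboveground,
        "soil": baseline_soil,
        "total": base_total,
        "aboveground_density": baseline_aboveground / canopy_area_ha,
        "soil_density": baseline_soil / canopy_area_ha,
        "total_density": base_total / canopy_area_ha,
    }
    future = {
        "aboveground": future_aboveground,
        "soil": future_soil,
        "total": fut_total,
        "aboveground_density": future_aboveground / canopy_area_ha,
        "soil_density": future_soil / canopy_area_ha,
        "total_density": fut_total / canopy_area_ha,
    }
    pct = {
        k: percent_change(baseline[k], future[k])
        for k in ("aboveground", "soil", "total")
        if baseline[k] != 0
    }
    assert np.isclose(baseline["total"], baseline["aboveground"] + baseline["soil"])
    assert np.isclose(future["total"], future["aboveground"] + future["soil"])
    return ScenarioSummary(
        canopy_area_ha=canopy_area_ha, baseline=baseline, future=future, pct_change=pct
    )
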