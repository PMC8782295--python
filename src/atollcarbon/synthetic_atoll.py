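"""Seed-reproducible synthetic atoll scenes with known ground truth.

The generator emulates the spatial products a whole-atoll carbon budget
consumes — islet polygons, a categorical vegetation-community raster, a tree
species raster, crown records, a LIDAR-like elevation surface — plus the
field tables (stratified soil samples, nearshore DOC samples, per-species
transect diameter lists).  Community class proportions default to the
published vegetated-area composition; every stochastic quantity is drawn
from a named substream of one global seed, so scenes are bit-reproducible
and every downstream stage can be tested against generator truth.

Islets are random convex blobs scaled to exact target areas: their shape is
irrelevant to the accounting, their area is not.  Soil %C noise is lognormal
around stratum means (%C is positive and right-skewed); elevation is a 2 m
base (the sea-level offset the height model subtracts back off) plus canopy
height plus noise, with an optional nodata patch emulating an elevation-data
gap on one islet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Point, Polygon

from . import reference
from .aboveground_carbon import AllometryParams, TreeRecord, agb, tree_carbon
from .doc_runoff import CANOPY_CN, CANOPY_NATIVE, DOCSample, INTERTIDAL
from .soil_carbon import SoilSample, StockParams, stock_formula
from .spatial_core import (
    BARE_GROUND,
    BLANK,
    FIRST_CLASS_CODE,
    GRASSLAND,
    RUNWAY,
    UNKNOWN,
    WATER,
    AtollScene,
    CategoricalRaster,
    ElevationSurface,
    GridSpec,
    build_legend,
    canopy_area,
)

# substream offsets: one global seed fans out per stage
_STREAM = {
    "islets": 11, "community": 12, "species": 13, "landcover": 14,
    "crowns": 15, "elevation": 16, "soil": 17, "doc": 18, "transects": 19,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stage], seed])


#: grassland community (no woody species; excluded from canopy area)
GRASS_COMMUNITY = "Lepturus repens/Fimbristylis cymosa"

#: community -> woody species composition (label, proportion)
COMMUNITY_SPECIES = {
    "C. nucifera": (("Cocos nucifera", 1.0),),
    "C. nucifera/H. foertherianum": (
        ("Cocos nucifera", 0.5), ("Heliotropium foertherianum", 0.5),
    ),
    "H. foertherianum/S. sericea": (
        ("Heliotropium foertherianum", 0.5), ("Scaevola sericea", 0.5),
    ),
    "H. tiliaceus": (("Hibiscus tiliaceus", 1.0),),
    GRASS_COMMUNITY: (),
    "P. tectorius": (("Pandanus tectorius", 1.0),),
    "P. grandis": (("Pisonia grandis", 1.0),),
    "P. grandis/H. foertherianum": (
        ("Pisonia grandis", 0.5), ("Heliotropium foertherianum", 0.5),
    ),
    "S. sericea/H. foertherianum": (
        ("Scaevola sericea", 0.5), ("Heliotropium foertherianum", 0.5),
    ),
    "Other": (("Cordia subcordata", 0.5), ("Terminalia catappa", 0.5)),
}

DEFAULT_COMMUNITY_MIX = {
    c: pct for c, (_, pct) in reference.SOIL_SAMPLES_BY_COMMUNITY.items()
}

# species height means/sds (m) and stem diameter means/sds (cm): realistic
# stature ordering for an atoll forest (palms tallest, beach shrubs shortest)
DEFAULT_HEIGHT_MEANS = {
    "Cocos nucifera": 18.0, "Cordia subcordata": 9.0,
    "Heliotropium foertherianum": 6.0, "Hibiscus tiliaceus": 8.0,
    "Pandanus tectorius": 8.0, "Pisonia grandis": 12.0,
    "Scaevola sericea": 3.0, "Terminalia catappa": 15.0,
}
DEFAULT_HEIGHT_SDS = {sp: 0.15 * h for sp, h in DEFAULT_HEIGHT_MEANS.items()}
DEFAULT_DIAMETER_MEANS = {
    "Cocos nucifera": 30.0, "Cordia subcordata": 25.0,
    "Heliotropium foertherianum": 15.0, "Hibiscus tiliaceus": 20.0,
    "Pandanus tectorius": 20.0, "Pisonia grandis": 35.0,
    "Scaevola sericea": 8.0, "Terminalia catappa": 40.0,
}
DEFAULT_DIAMETER_SDS = {sp: 0.2 * d for sp, d in DEFAULT_DIAMETER_MEANS.items()}


@dataclass
class SceneConfig:
    n_islets: int = 8
    islet_area_range_ha: tuple[float, float] = (0.25, 12.0)
    cell_size: float = 2.0
    land_fraction: float = 0.22  # emergent land share of the grid
    community_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMMUNITY_MIX)
    )
    species_height_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEIGHT_MEANS)
    )
    species_height_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEIGHT_SDS)
    )
    species_diameter_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIAMETER_MEANS)
    )
    species_diameter_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIAMETER_SDS)
    )
    crown_rate: float = 0.06  # crowns per tree-bearing cell
    runway_fraction: float = 0.03  # of land cells, on the largest islet
    bare_fraction: float = 0.02
    unknown_fraction: float = 0.01
    elevation_noise_sd: float = 0.2  # m
    transformation_coverage: float = 0.95
    lidar_gap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.community_mix.values())
        # the published composition column sums to 100.1%; accept percent or
        # fraction inputs within +-0.5% and normalize exactly
        if not (0.995 <= total <= 1.005 or 99.5 <= total <= 100.5):
            raise ValueError("community proportions must sum to 1 (or 100%)")
        self.community_mix = {c: p / total for c, p in self.community_mix.items()}
        if not 0 <= self.transformation_coverage <= 1:
            raise ValueError("transformation_coverage must lie in [0, 1]")
        if self.n_islets < 1:
            raise ValueError("need at least one islet")


@dataclass
class SoilTruth:
    """Generator truth for soil: per-community mean %C and bulk density.

    Higher %C (and lower bulk density) under native *Pisonia*-bearing
    canopies encodes the seabird-subsidy pattern the study measured.
    """

    mean_c_pct: dict[str, float] = field(
        default_factory=lambda: {
            "C. nucifera": 3.5,
            "C. nucifera/H. foertherianum": 4.5,
            "H. foertherianum/S. sericea": 5.0,
            "H. tiliaceus": 4.0,
            GRASS_COMMUNITY: 2.0,
            "P. tectorius": 5.0,
            "P. grandis": 12.0,
            "P. grandis/H. foertherianum": 14.0,
            "S. sericea/H. foertherianum": 4.5,
            "Other": 4.0,
        }
    )
    bulk_density: dict[str, float] = field(
        default_factory=lambda: {
            "C. nucifera": 1.1,
            "C. nucifera/H. foertherianum": 1.0,
            "H. foertherianum/S. sericea": 1.0,
            "H. tiliaceus": 1.0,
            GRASS_COMMUNITY: 1.3,
            "P. tectorius": 0.9,
            "P. grandis": 0.45,
            "P. grandis/H. foertherianum": 0.40,
            "S. sericea/H. foertherianum": 1.0,
            "Other": 1.0,
        }
    )
    bin_thresholds: tuple[float, float] = (10.0, 20.0)
    c_noise_sigma: float = 0.35  # lognormal sigma around the stratum mean
    bd_noise_sd: float = 0.10

    def __post_init__(self) -> None:
        for c, m in self.mean_c_pct.items():
            if not 0 <= m <= 100:
                raise ValueError(f"mean %C for {c} out of [0, 100]")
        if any(v <= 0 for v in self.bulk_density.values()):
            raise ValueError("bulk densities must be positive")


@dataclass
class DOCTruth:
    """Generator truth for nearshore DOC (uM C).

    Group means are the published canopy-group means; the between- and
    within-site standard deviations are synthetic choices (the study prints
    none), sized so site differences dominate replicate noise.
    """

    cn_mean: float = reference.DOC_GROUP_MEANS["c_nucifera"]
    native_mean: float = reference.DOC_GROUP_MEANS["native"]
    between_site_sd: float = 12.0
    within_site_sd: float = 5.0
    samples_per_site: int = 2
    controlled_mean: float = reference.DOC_COMPARISON_MEANS["recently_controlled_site"]

    def __post_init__(self) -> None:
        if self.cn_mean <= 0 or self.native_mean <= 0:
            raise ValueError("DOC means must be positive")
        if self.between_site_sd < 0 or self.within_site_sd < 0:
            raise ValueError("DOC sds must be non-negative")


@dataclass
class SceneTruth:
    """Everything needed for parameter-recovery tests against the generator."""

    config: SceneConfig
    islet_areas_ha: dict[str, float]
    community_proportions: dict[str, float]  # realized, over vegetated cells
    crown_species: list[str]
    crown_true_heights: list[float]
    transect_diameters: dict[str, np.ndarray]
    canopy_area_ha: float
    transformation_polygons: list[Polygon]
    gap_islet: str | None

    def true_aboveground_total_mg(
        self,
        bwd_means: dict[str, float] | None = None,
        params: AllometryParams = AllometryParams(),
    ) -> float:
        """True aboveground carbon (Mg C) from true heights and species
        quadratic-mean diameters."""
        bwd_means = reference.BWD_MEANS if bwd_means is None else bwd_means
        qmd = {
            sp: float(np.sqrt(np.mean(d**2)))
            for sp, d in self.transect_diameters.items()
        }
        total_kg = 0.0
        for sp, h in zip(self.crown_species, self.crown_true_heights):
            if sp in bwd_means:
                total_kg += tree_carbon(agb(bwd_means[sp], qmd[sp], h, params), params)
        return total_kg / 1000.0


def true_soil_total_mg(
    scene: AtollScene, truth: SoilTruth, params: StockParams = StockParams()
) -> float:
    """Generator-truth soil stock: per-cell community truth through the stock
    formula (sentinel cells contribute zero)."""
    legend = scene.community_raster.legend
    cell_ha = scene.grid.cell_area_ha
    total = 0.0
    codes, counts = np.unique(scene.community_raster.codes, return_counts=True)
    for code, n in zip(codes, counts):
        label = legend[int(code)]
        if label not in truth.mean_c_pct:
            continue
        total += stock_formula(
            truth.mean_c_pct[label], truth.bulk_density[label],
            params.depth_cm, float(n) * cell_ha,
        )
    return total


def _islet_polygon(rng: np.random.Generator, area_m2: float, center: tuple[float, float]) -> Polygon:
    """Random convex blob scaled to the exact target area."""
    r = math.sqrt(area_m2 / math.pi)
    angles = np.sort(rng.uniform(0, 2 * math.pi, 14))
    radii = r * rng.uniform(0.7, 1.3, angles.size)
    pts = np.c_[center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)]
    hull = shapely.convex_hull(shapely.multipoints(pts))
    factor = math.sqrt(area_m2 / hull.area)
    return affinity.scale(hull, xfact=factor, yfact=factor, origin="centroid")


def generate_scene(config: SceneConfig) -> tuple[AtollScene, SceneTruth]:
    """Build a synthetic atoll scene; deterministic for a fixed config seed."""
    seed = config.seed
    rng_isl = _rng(seed, "islets")

    lo, hi = config.islet_area_range_ha
    areas_ha = np.exp(rng_isl.uniform(np.log(lo), np.log(hi), config.n_islets))
    areas_ha = np.sort(areas_ha)[::-1]
    total_land_m2 = areas_ha.sum() * 1e4

    grid_area = total_land_m2 / config.land_fraction
    width_m = math.sqrt(grid_area * 4.0 / 3.0)
    height_m = grid_area / width_m
    s = config.cell_size
    grid = GridSpec(
        origin=(0.0, height_m), cell_size=s,
        width=int(math.ceil(width_m / s)), height=int(math.ceil(height_m / s)),
    )

    # place islets by rejection on bounding circles
    islets: list[tuple[str, Polygon, float]] = []
    placed: list[tuple[float, float, float]] = []
    for i, a in enumerate(areas_ha):
        r = math.sqrt(a * 1e4 / math.pi) * 1.3
        ok = False
        for margin in (2 * s, 0.0, -0.15 * r):  # progressively relax spacing
            for _ in range(500):
                cx = rng_isl.uniform(r, max(r + s, width_m - r))
                cy = rng_isl.uniform(r, max(r + s, height_m - r))
                if all(
                    math.hypot(cx - px, cy - py) > r + pr + margin
                    for px, py, pr in placed
                ):
                    ok = True
                    break
            if ok:
                break
        if not ok:
            raise ValueError("could not place islets; reduce areas or count")
        placed.append((cx, cy, r))
        poly = _islet_polygon(rng_isl, a * 1e4, (cx, cy))
        islets.append((f"Islet-{i:02d}", poly, poly.area / 1e4))

    xs, ys = grid.cell_centers()
    flat_x, flat_y = xs.ravel(), ys.ravel()
    islet_id = np.full(flat_x.size, -1, dtype=np.int32)
    for i, (_, poly, _) in enumerate(islets):
        inside = shapely.contains_xy(poly, flat_x, flat_y)
        islet_id[inside] = i
    islet_id = islet_id.reshape(xs.shape)
    land = islet_id >= 0
    n_land = int(land.sum())
    if n_land == 0:
        raise ValueError("infeasible config: no land cells on the grid")

    # community raster over land cells
    rng_comm = _rng(seed, "community")
    communities = sorted(config.community_mix)
    probs = np.array([config.community_mix[c] for c in communities])
    legend = build_legend(communities)
    code_of = {v: k for k, v in legend.items()}
    comm_codes = np.full(xs.shape, WATER, dtype=np.int32)
    draw = rng_comm.choice(len(communities), size=n_land, p=probs)
    comm_codes[land] = np.array([code_of[communities[k]] for k in range(len(communities))])[draw]

    # landcover overrides: runway strip on the largest islet, scattered bare
    # ground and unknown cells
    rng_lc = _rng(seed, "landcover")
    land_idx = np.flatnonzero(land.ravel())
    n_runway = int(config.runway_fraction * n_land)
    runway_cells = np.array([], dtype=int)
    big = np.flatnonzero((islet_id == 0).ravel())
    if n_runway > 0 and big.size:
        order = np.argsort(flat_y[big])  # contiguous south strip
        runway_cells = big[order[: min(n_runway, big.size)]]
    n_bare = int(config.bare_fraction * n_land)
    n_unknown = int(config.unknown_fraction * n_land)
    rest = np.setdiff1d(land_idx, runway_cells)
    scattered = rng_lc.choice(rest, size=min(n_bare + n_unknown, rest.size), replace=False)
    bare_cells, unknown_cells = scattered[:n_bare], scattered[n_bare:]

    for cells, code in ((runway_cells, RUNWAY), (bare_cells, BARE_GROUND), (unknown_cells, UNKNOWN)):
        comm_codes.ravel()[cells] = code

    grass_code = code_of.get(GRASS_COMMUNITY)
    grass = (
        comm_codes == grass_code if grass_code is not None
        else np.zeros_like(comm_codes, dtype=bool)
    )
    landcover_codes = np.full(xs.shape, WATER, dtype=np.int32)
    canopy_code = FIRST_CLASS_CODE
    landcover_codes[land] = canopy_code
    landcover_codes[grass] = GRASSLAND
    for cells, code in ((runway_cells, RUNWAY), (bare_cells, BARE_GROUND), (unknown_cells, UNKNOWN)):
        landcover_codes.ravel()[cells] = code
    landcover = CategoricalRaster(
        grid=grid, codes=landcover_codes,
        legend={**{k: v for k, v in legend.items() if k < FIRST_CLASS_CODE}, canopy_code: "canopy"},
    )

    # species raster from community composition
    rng_sp = _rng(seed, "species")
    species_labels = sorted(reference.BIOMASS_SPECIES)
    sp_legend = build_legend(species_labels)
    sp_code_of = {v: k for k, v in sp_legend.items()}
    sp_codes = np.full(xs.shape, WATER, dtype=np.int32)
    sp_codes[land] = BLANK
    for comm in communities:
        comp = COMMUNITY_SPECIES[comm]
        sel = comm_codes == code_of[comm]
        n_sel = int(sel.sum())
        if not comp or n_sel == 0:
            continue
        sp_names = [sp for sp, _ in comp]
        sp_probs = np.array([p for _, p in comp])
        pick = rng_sp.choice(len(sp_names), size=n_sel, p=sp_probs / sp_probs.sum())
        sp_codes[sel] = np.array([sp_code_of[n] for n in sp_names])[pick]

    community_raster = CategoricalRaster(grid=grid, codes=comm_codes, legend=legend)
    species_raster = CategoricalRaster(grid=grid, codes=sp_codes, legend=sp_legend)

    # crowns on tree-bearing canopy cells
    rng_cr = _rng(seed, "crowns")
    treed = (sp_codes >= FIRST_CLASS_CODE) & (landcover_codes == canopy_code)
    tree_cells = np.flatnonzero(treed.ravel())
    n_crowns = rng_cr.binomial(tree_cells.size, config.crown_rate)
    crown_cells = np.sort(rng_cr.choice(tree_cells, size=n_crowns, replace=False))
    crown_species: list[str] = []
    crown_heights: list[float] = []
    crowns: list[TreeRecord] = []
    for cell in crown_cells:
        sp = sp_legend[int(sp_codes.ravel()[cell])]
        h = max(1.0, rng_cr.normal(config.species_height_means[sp], config.species_height_sds[sp]))
        cx, cy = flat_x[cell], flat_y[cell]
        geom = Point(cx, cy).buffer(s * 0.45, quad_segs=2)
        crowns.append(TreeRecord(species=sp, geometry=geom))
        crown_species.append(sp)
        crown_heights.append(float(h))

    # elevation: 2 m base + canopy height at crown cells + noise
    rng_el = _rng(seed, "elevation")
    elev = np.zeros(xs.shape)
    elev[land] = 2.0
    elev += rng_el.normal(0.0, config.elevation_noise_sd, xs.shape) * land
    flat_elev = elev.ravel()
    flat_elev[crown_cells] = 2.0 + np.asarray(crown_heights)  # exact canopy top
    nodata = ~land
    gap_islet = None
    if config.lidar_gap and len(islets) > 1:
        gap_idx = len(islets) // 2
        gap_islet = islets[gap_idx][0]
        nodata = nodata | (islet_id == gap_idx)
    elevation = ElevationSurface(grid=grid, values=elev, nodata=nodata)

    # transformation polygons: each islet shrunk about its centroid so that
    # covered area / emergent area equals the configured coverage
    f = math.sqrt(config.transformation_coverage)
    transformation = [
        affinity.scale(poly, xfact=f, yfact=f, origin="centroid")
        for _, poly, _ in islets
    ]

    rng_tr = _rng(seed, "transects")
    transects = {
        sp: np.maximum(
            1.0,
            rng_tr.normal(
                config.species_diameter_means[sp],
                config.species_diameter_sds[sp],
                30,
            ),
        )
        for sp in species_labels
    }

    scene = AtollScene(
        islets=islets,
        community_raster=community_raster,
        species_raster=species_raster,
        landcover=landcover,
        elevation=elevation,
        crowns=crowns,
    )

    veg = comm_codes >= FIRST_CLASS_CODE
    realized = {
        legend[int(c)]: n / veg.sum()
        for c, n in zip(*np.unique(comm_codes[veg], return_counts=True))
    }
    truth = SceneTruth(
        config=config,
        islet_areas_ha={name: a for name, _, a in islets},
        community_proportions=realized,
        crown_species=crown_species,
        crown_true_heights=crown_heights,
        transect_diameters=transects,
        canopy_area_ha=canopy_area(landcover),
        transformation_polygons=transformation,
        gap_islet=gap_islet,
    )
    return scene, truth


def sample_soil(
    scene: AtollScene,
    truth: SoilTruth,
    n_sites: int = reference.TOTAL_SOIL_SITES,
    seed: int = 0,
    n_2016: int | None = None,
) -> list[SoilSample]:
    """Stratified soil sampling over islet x community.

    Sites are allocated to strata proportionally to stratum cell counts (at
    least one per stratum while the budget allows, largest strata first).
    %C is lognormal around the stratum truth mean; bulk density is Gaussian
    around the community truth.  Samples beyond the first ``n_2016`` emulate
    the later campaign: total carbon only, organic left missing for
    imputation.  Labels are read from the rasters at the sampled cell.
    """
    rng = _rng(seed, "soil")
    grid = scene.grid
    comm = scene.community_raster
    spec = scene.species_raster
    if n_2016 is None:
        n_2016 = int(round(n_sites * reference.SOIL_SITES_2016 / reference.TOTAL_SOIL_SITES))

    islet_lookup = {}
    xs, ys = grid.cell_centers()
    flat_x, flat_y = xs.ravel(), ys.ravel()
    islet_id = np.full(flat_x.size, -1, dtype=np.int32)
    for i, (_, poly, _) in enumerate(scene.islets):
        islet_id[shapely.contains_xy(poly, flat_x, flat_y)] = i
        islet_lookup[i] = scene.islets[i][0]

    veg = comm.codes.ravel() >= FIRST_CLASS_CODE
    strata: dict[tuple[int, int], np.ndarray] = {}
    keys = islet_id.astype(np.int64) * 1000 + comm.codes.ravel()
    for key in np.unique(keys[veg & (islet_id >= 0)]):
        cells = np.flatnonzero((keys == key) & veg & (islet_id >= 0))
        strata[(int(key // 1000), int(key % 1000))] = cells
    if not strata:
        raise ValueError("scene has no vegetated cells to sample")

    # proportional allocation with a one-site floor, largest remainder
    sizes = {k: v.size for k, v in strata.items()}
    total_cells = sum(sizes.values())
    alloc = {k: 0 for k in strata}
    order = sorted(strata, key=lambda k: -sizes[k])
    if n_sites >= len(strata):
        for k in order:
            alloc[k] = 1
        remaining = n_sites - len(strata)
        quotas = {k: remaining * sizes[k] / total_cells for k in order}
        for k in order:
            alloc[k] += int(quotas[k])
        leftovers = n_sites - sum(alloc.values())
        frac_order = sorted(order, key=lambda k: -(quotas[k] - int(quotas[k])))
        for k in frac_order[:leftovers]:
            alloc[k] += 1
    else:
        for k in order[:n_sites]:
            alloc[k] = 1

    samples: list[SoilSample] = []
    site_no = 0
    for k in order:
        cells = rng.choice(strata[k], size=min(alloc[k], strata[k].size), replace=False)
        for cell in np.atleast_1d(cells):
            community = comm.legend[int(comm.codes.ravel()[cell])]
            species = spec.legend[int(spec.codes.ravel()[cell])]
            mean_c = truth.mean_c_pct[community]
            if truth.c_noise_sigma > 0:
                sigma = truth.c_noise_sigma
                organic = float(
                    rng.lognormal(math.log(mean_c) - sigma**2 / 2.0, sigma)
                )
            else:
                organic = mean_c
            organic = float(np.clip(organic, 0.05, 95.0))
            bd = float(
                max(0.05, rng.normal(truth.bulk_density[community], truth.bd_noise_sd))
            )
            # total carbon: organic plus a small carbonate fraction
            inorganic = float(rng.uniform(0.2, 1.0)) if truth.c_noise_sigma > 0 else 0.0
            total_c = min(100.0, organic + inorganic)
            year = 2016 if site_no < n_2016 else 2019
            samples.append(
                SoilSample(
                    site_id=f"S{site_no:03d}",
                    islet=islet_lookup[k[0]],
                    year=year,
                    community=community,
                    species=species,
                    total_c_pct=total_c,
                    organic_c_pct=organic if year == 2016 else None,
                    bulk_density=bd,
                    location=(float(flat_x[cell]), float(flat_y[cell])),
                )
            )
            site_no += 1
    return samples


def sample_doc(
    scene: AtollScene,
    truth: DOCTruth,
    n_sites: int = reference.DOC_N_SITES,
    seed: int = 0,
    n_controlled: int = 0,
) -> list[DOCSample]:
    """Nearshore DOC sampling: half the sites adjacent to *C. nucifera*
    canopy, half to native canopy, a random site intercept (between-site sd)
    plus per-sample noise, two samples per site.  The first ``n_controlled``
    palm sites are flagged recently-controlled and draw from the lowered
    post-control mean."""
    rng = _rng(seed, "doc")
    comm = scene.community_raster
    veg_codes = comm.codes.ravel()
    cn_classes = [
        code for code, label in comm.legend.items() if label.startswith("C. nucifera")
    ]
    native_classes = [
        code
        for code, label in comm.legend.items()
        if code >= FIRST_CLASS_CODE and code not in cn_classes and label != GRASS_COMMUNITY
    ]
    cn_cells = np.flatnonzero(np.isin(veg_codes, cn_classes))
    native_cells = np.flatnonzero(np.isin(veg_codes, native_classes))
    if cn_cells.size == 0 or native_cells.size == 0:
        raise ValueError("scene lacks one of the shoreline canopy types")

    xs, ys = scene.grid.cell_centers()
    flat_x, flat_y = xs.ravel(), ys.ravel()
    n_cn = n_sites // 2
    samples: list[DOCSample] = []
    for i in range(n_sites):
        is_cn = i < n_cn
        cell = int(rng.choice(cn_cells if is_cn else native_cells))
        canopy = CANOPY_CN if is_cn else CANOPY_NATIVE
        controlled = is_cn and i < n_controlled
        mean = truth.controlled_mean if controlled else (
            truth.cn_mean if is_cn else truth.native_mean
        )
        intercept = rng.normal(0.0, truth.between_site_sd)
        habitat = INTERTIDAL[i % 2]
        for j in range(truth.samples_per_site):
            doc = max(1.0, mean + intercept + rng.normal(0.0, truth.within_site_sd))
            samples.append(
                DOCSample(
                    site_id=f"D{i:02d}",
                    islet="synthetic",
                    habitat=habitat,
                    adjacent_canopy=canopy,
                    doc=float(doc),
                    management_status="recently_controlled" if controlled else "intact",
                    position=(float(flat_x[cell]), float(flat_y[cell]) ),
                )
            )
    return samples
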