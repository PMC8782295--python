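"""Per-tree aboveground biomass and carbon via tropical allometry.

Each tree crown contributes AGB = 0.0673 * (rho * D^2 * H)^0.976 kg, where
rho is the species' mean basic wood density (g cm^-3), D the species
quadratic-mean diameter (cm) and H the tree height (m).  Heights come from
the elevation surface at the crown centroid minus a 2 m sea-level offset,
falling back to the species' study-wide mean height inside elevation-data
gaps (or when the subtraction yields a non-positive height).  Biomass
converts to carbon with a 0.47 multiplier.  Only the eight dominant
biomass-bearing species carry biomass; crowns of other labels contribute
zero and are counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .reference import BIOMASS_SPECIES, BWD_MEANS
from .spatial_core import ElevationSurface, crown_centroid

logger = logging.getLogger(__name__)

KG_PER_MG = 1000.0


@dataclass(frozen=True)
class AllometryParams:
    coefficient: float = 0.0673
    exponent: float = 0.976
    carbon_fraction: float = 0.47
    sea_level_offset: float = 2.0  # m subtracted from elevation to get height

    def __post_init__(self) -> None:
        if min(self.coefficient, self.exponent, self.carbon_fraction) <= 0:
            raise ValueError("allometry parameters must be positive")


@dataclass
class TreeRecord:
    """One crown's accounting state."""

    species: str
    geometry: Polygon | None = None
    centroid: Point | None = None
    height: float | None = None
    height_source: str = ""  # "elevation" | "species_mean"
    diameter: float | None = None  # cm, species quadratic mean
    bwd: float | None = None  # g cm^-3
    agb: float | None = None  # kg
    carbon: float | None = None  # kg C

    def __post_init__(self) -> None:
        if self.centroid is None and self.geometry is not None:
            self.centroid = crown_centroid(self.geometry)


def quadratic_mean_diameter(diameters) -> float:
    """sqrt(mean of squared diameters); the stand basal-area-equivalent diameter."""
    arr = np.asarray(list(diameters), dtype=float)
    if arr.size == 0:
        raise ValueError("diameter list is empty")
    if (arr <= 0).any():
        raise ValueError("diameters must be positive")
    return float(np.sqrt(np.mean(arr**2)))


def tree_height(
    elevation: ElevationSurface,
    centroid: Point,
    params: AllometryParams,
    species_mean_heights: dict[str, float],
    species: str,
) -> tuple[float, str]:
    """(height m, source): elevation minus the sea-level offset, else species mean."""
    value = elevation.value_at(centroid.x, centroid.y)
    if value is not None:
        h = value - params.sea_level_offset
        if h > 0:
            return h, "elevation"
    mean = species_mean_heights.get(species)
    if mean is None:
        raise ValueError(f"no species mean height available for {species!r}")
    return mean, "species_mean"


def agb(bwd: float, diameter: float, height: float, params: AllometryParams = AllometryParams()) -> float:
    """Aboveground biomass in kg from density (g cm^-3), diameter (cm), height (m)."""
    if bwd <= 0 or diameter <= 0 or height <= 0:
        raise ValueError("bwd, diameter and height must all be positive")
    return params.coefficient * (bwd * diameter**2 * height) ** params.exponent


def tree_carbon(agb_kg: float, params: AllometryParams = AllometryParams()) -> float:
    if agb_kg < 0:
        raise ValueError("biomass cannot be negative")
    return params.carbon_fraction * agb_kg


def account_trees(
    crowns: list[TreeRecord],
    elevation: ElevationSurface,
    species_mean_heights: dict[str, float],
    species_diameters: dict[str, float],
    bwd_means: dict[str, float] | None = None,
    params: AllometryParams = AllometryParams(),
) -> list[TreeRecord]:
    """Fill heights, diameters, densities, biomass and carbon for every crown.

    Crowns of species outside the biomass-bearing set get zero biomass; their
    count is logged so narrative totals stay auditable.
    """
    bwd_means = BWD_MEANS if bwd_means is None else bwd_means
    skipped = 0
    for t in crowns:
        if t.species not in BIOMASS_SPECIES or t.species not in bwd_means:
            t.agb = 0.0
            t.carbon = 0.0
            skipped += 1
            continue
        if t.height is None:
            t.height, t.height_source = tree_height(
                elevation, t.centroid, params, species_mean_heights, t.species
            )
        if t.diameter is None:
            t.diameter = species_diameters[t.species]
        if t.bwd is None:
            t.bwd = bwd_means[t.species]
        t.agb = agb(t.bwd, t.diameter, t.height, params)
        t.carbon = tree_carbon(t.agb, params)
    if skipped:
        logger.info("%d crowns of non-biomass-bearing species contribute zero", skipped)
    return crowns


def aboveground_totals(crowns: list[TreeRecord], canopy_area_ha: float) -> pd.DataFrame:
    """Per-species and grand aboveground carbon totals (Mg C) and densities.

    Density normalizes by the canopy-bearing area, not total land area.
    """
    if canopy_area_ha <= 0:
        raise ValueError("canopy area must be positive")
    rows = [(t.species, (t.carbon or 0.0) / KG_PER_MG) for t in crowns]
    df = pd.DataFrame(rows, columns=["species", "carbon_mg"])
    per_species = df.groupby("species", sort=True)["carbon_mg"].agg(["sum", "count"])
    per_species.columns = ["total_mg_c", "n_trees"]
    grand = pd.DataFrame(
        {"total_mg_c": [per_species["total_mg_c"].sum()],
         "n_trees": [int(per_species["n_trees"].sum())]},
        index=["TOTAL"],
    )
    out = pd.concat([per_species, grand])
    out["density_mg_c_ha"] = out["total_mg_c"] / canopy_area_ha
    return out
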