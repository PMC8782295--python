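"""Basic wood density (BWD) from disc measurements, with green-volume correction.

Basic wood density is oven-dry mass over green (fully swollen) volume — the
convention used by tropical allometry databases.  Field discs are measured in
two states: at the fiber saturation point (FSP; submerged 24 h, dimensions
only) and anhydrous (dimensions and mass).  When the saturated dimensions are
available the green volume is taken directly from them; otherwise the dry
volume is inflated by the species' volumetric shrinkage ``S`` (fractional
volume loss from green to oven-dry), ``V_green = V_dry / (1 - S)``.

Because shrinkage coefficients were not measurable in the field, a single
tropical-species mean coefficient pair is applied to all species, with
genus-specific values for *Pisonia*.  The numeric defaults in
``DEFAULT_COEFFICIENTS`` are representative literature-scale estimates and
can be overridden per species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DiscMeasurement:
    """One wood disc, measured saturated and anhydrous (cm / g)."""

    species: str
    sample_id: str
    anhydrous_diameter: float
    anhydrous_width: float
    anhydrous_mass: float
    saturated_diameter: float | None = None
    saturated_width: float | None = None

    def __post_init__(self) -> None:
        if self.anhydrous_mass <= 0:
            raise ValueError("anhydrous mass must be positive")
        if self.saturated_diameter is not None:
            if (
                self.saturated_diameter < self.anhydrous_diameter
                or (self.saturated_width or 0) < self.anhydrous_width
            ):
                raise ValueError("saturated dimensions must be >= anhydrous dimensions")


@dataclass(frozen=True)
class CorrectionCoefficients:
    """Fiber saturation point and volumetric shrinkage, both fractions in (0,1)."""

    species: str
    fiber_saturation_point: float
    volumetric_shrinkage: float
    source: str = "tropical-mean"

    def __post_init__(self) -> None:
        for name in ("fiber_saturation_point", "volumetric_shrinkage"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


# Tropical-mean pair for all species; genus-specific pair for Pisonia.
# Representative estimates (editable), not field measurements.
_TROPICAL_MEAN = (0.28, 0.12)
_PISONIA = (0.40, 0.10)


def default_coefficients(species: str) -> CorrectionCoefficients:
    if species.split()[0].lower() == "pisonia":
        fsp, shrink = _PISONIA
        return CorrectionCoefficients(species, fsp, shrink, source="genus-specific")
    fsp, shrink = _TROPICAL_MEAN
    return CorrectionCoefficients(species, fsp, shrink)


DEFAULT_COEFFICIENTS = default_coefficients


@dataclass
class BWDEntry:
    """Per-species pooled BWD summary (min/mean/max in g cm^-3)."""

    species: str
    bwd_min: float
    bwd_mean: float
    bwd_max: float
    se: float | None
    sample_size: int
    field_n: int
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.bwd_min <= self.bwd_mean <= self.bwd_max):
            raise ValueError("require 0 < min <= mean <= max")


def disc_volume(diameter: float, width: float) -> float:
    """Cylinder volume of a disc, cm^3."""
    if diameter <= 0 or width <= 0:
        raise ValueError("diameter and width must be positive")
    return math.pi * (diameter / 2.0) ** 2 * width


def correct_bwd(m: DiscMeasurement, coeff: CorrectionCoefficients) -> float:
    """Basic wood density of one disc: anhydrous mass over green volume.

    Green volume is the saturated-disc cylinder volume when measured;
    otherwise the anhydrous volume inflated by volumetric shrinkage.
    """
    if coeff.volumetric_shrinkage >= 1:
        raise ValueError("volumetric shrinkage must be < 1")
    if m.saturated_diameter is not None and m.saturated_width is not None:
        v_green = disc_volume(m.saturated_diameter, m.saturated_width)
    else:
        v_dry = disc_volume(m.anhydrous_diameter, m.anhydrous_width)
        v_green = v_dry / (1.0 - coeff.volumetric_shrinkage)
    return m.anhydrous_mass / v_green


def density_12pct_to_basic(rho_12: float, coeff: CorrectionCoefficients) -> float:
    """Convert an air-dry (12% moisture content) density to basic density.

    Below the FSP, wood volume shrinks linearly with moisture content:
    ``V(mc) = V_green * (1 - S*(1 - mc/FSP))``.  With mass at 12% moisture
    equal to ``1.12 x`` dry mass,

        rho_basic = rho_12 * (1 - S*(1 - 0.12/FSP)) / 1.12

    Used to harmonize literature densities reported on the 12%-moisture basis.
    """
    mc = 0.12
    fsp = coeff.fiber_saturation_point
    s = coeff.volumetric_shrinkage
    shrink_at_mc = s * (1.0 - min(mc, fsp) / fsp)
    return rho_12 * (1.0 - shrink_at_mc) / (1.0 + mc)


def merge_bwd(
    species: str,
    field_values: list[float],
    literature: list[tuple[float, str]] = (),
) -> BWDEntry | None:
    """Pool corrected field densities with literature values into one entry.

    Min/max/mean/SE are taken over the pooled values; ``sample_size`` is the
    pooled count and ``field_n`` the number of field discs.  Returns ``None``
    (with a warning) when the pool is empty.
    """
    pool = list(field_values) + [v for v, _ in literature]
    if not pool:
        warnings.warn(f"no BWD values for {species}; species omitted")
        return None
    arr = np.asarray(pool, dtype=float)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else None
    sources = tuple(dict.fromkeys(s for _, s in literature))
    if field_values:
        sources = ("field",) + sources
    return BWDEntry(
        species=species,
        bwd_min=float(arr.min()),
        bwd_mean=float(arr.mean()),
        bwd_max=float(arr.max()),
        se=se,
        sample_size=len(arr),
        field_n=len(field_values),
        sources=sources,
    )
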