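"""Shared spatial data model: grids, categorical rasters, elevation, polygons.

Coordinates are planar metres in a local projected frame.  Cell indexing is
row-major with the origin at the upper-left corner of the grid; cell
``(row, col)`` covers the half-open box ``[x0 + col*s, x0 + (col+1)*s) x
(y0 - (row+1)*s, y0 - row*s]`` where ``s`` is the cell size.  Polygon areas
are reported in hectares.

Categorical rasters reserve a block of sentinel codes (blank, water, unknown,
runway, bare ground, grassland) that are distinct from vegetation classes;
the distinction matters because shoreline pixels over water, the runway, and
unvegetated ground are excluded from carbon accounting and from the canopy
area that normalizes carbon densities.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, mapping, shape

# Sentinel codes shared by every categorical raster.  Vegetation / species
# classes are assigned codes >= FIRST_CLASS_CODE in legend-sorted order.
BLANK = 0
WATER = 1
UNKNOWN = 2
RUNWAY = 3
BARE_GROUND = 4
GRASSLAND = 5
FIRST_CLASS_CODE = 10

SENTINEL_LEGEND = {
    BLANK: "",
    WATER: "water",
    UNKNOWN: "unknown",
    RUNWAY: "runway",
    BARE_GROUND: "bare_ground",
    GRASSLAND: "grassland",
}

#: land-cover classes excluded from the canopy area (besides water/blank)
CANOPY_EXCLUDED = frozenset({UNKNOWN, RUNWAY, BARE_GROUND, GRASSLAND})

SQM_PER_HA = 10_000.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid (origin at the upper-left corner)."""

    origin: tuple[float, float]
    cell_size: float
    width: int
    height: int
    crs_label: str = "local-metres"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / SQM_PER_HA

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        s = self.cell_size
        return (x0 + col * s, y0 - (row + 1) * s, x0 + (col + 1) * s, y0 - row * s)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped (height, width)."""
        x0, y0 = self.origin
        s = self.cell_size
        xs = x0 + (np.arange(self.width) + 0.5) * s
        ys = y0 - (np.arange(self.height) + 0.5) * s
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y); raises if outside the grid."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        if not (0 <= col < self.width and 0 <= row < self.height):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col


@dataclass
class CategoricalRaster:
    grid: GridSpec
    codes: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.shape != (self.grid.height, self.grid.width):
            raise ValueError("codes shape does not match grid")
        present = set(np.unique(self.codes).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"codes {sorted(missing)} missing from legend")

    def label_at(self, x: float, y: float) -> str:
        row, col = self.grid.index_of(x, y)
        return self.legend[int(self.codes[row, col])]

    def class_areas_ha(self) -> dict[str, float]:
        """Per-label summed cell area in hectares."""
        codes, counts = np.unique(self.codes, return_counts=True)
        a = self.grid.cell_area_ha
        return {self.legend[int(c)]: int(n) * a for c, n in zip(codes, counts)}


@dataclass
class ElevationSurface:
    grid: GridSpec
    values: np.ndarray
    nodata: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        if self.values.shape != (self.grid.height, self.grid.width):
            raise ValueError("values shape does not match grid")
        if self.nodata.shape != self.values.shape:
            raise ValueError("nodata mask shape does not match values")

    def value_at(self, x: float, y: float) -> float | None:
        """Elevation at a point, or None inside a nodata gap."""
        row, col = self.grid.index_of(x, y)
        if self.nodata[row, col]:
            return None
        return float(self.values[row, col])


@dataclass
class AttributedPolygon:
    """A polygon carrying community and/or species labels; blank where absent."""

    geometry: Polygon
    community: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.geometry.is_empty or self.geometry.area <= 0:
            raise ValueError("polygon must have positive area")

    @property
    def area_ha(self) -> float:
        return self.geometry.area / SQM_PER_HA


@dataclass
class AtollScene:
    """All spatial layers of one atoll snapshot, sharing a single grid."""

    islets: list[tuple[str, Polygon, float]]  # (name, geometry, area ha)
    community_raster: CategoricalRaster
    species_raster: CategoricalRaster
    landcover: CategoricalRaster
    elevation: ElevationSurface
    crowns: list = field(default_factory=list)  # list[TreeRecord]

    def __post_init__(self) -> None:
        g = self.community_raster.grid
        for layer in (self.species_raster, self.landcover):
            if layer.grid != g:
                raise ValueError("all rasters must share one GridSpec")
        if self.elevation.grid != g:
            raise ValueError("elevation must share the raster grid")

    @property
    def grid(self) -> GridSpec:
        return self.community_raster.grid


def build_legend(labels) -> dict[int, str]:
    """Legend with sentinel codes plus vegetation classes from FIRST_CLASS_CODE up.

    Class codes are assigned in sorted label order so that legends — and the
    lowest-code majority tie-break — are deterministic.
    """
    legend = dict(SENTINEL_LEGEND)
    clean = sorted({l for l in labels if l and l not in SENTINEL_LEGEND.values()})
    for i, label in enumerate(clean):
        legend[FIRST_CLASS_CODE + i] = label
    return legend


def _cell_boxes(grid: GridSpec, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    x0, y0 = grid.origin
    s = grid.cell_size
    return shapely.box(
        x0 + cols * s, y0 - (rows + 1) * s, x0 + (cols + 1) * s, y0 - rows * s
    )


def rasterize_majority(
    polygons: list[AttributedPolygon], grid: GridSpec, attribute: str
) -> CategoricalRaster:
    """Rasterize possibly-overlapping polygons by per-cell majority coverage.

    Each cell receives the attribute label covering the largest fraction of
    the cell (exact polygon-cell intersection areas); coverage of polygons
    sharing a label is pooled.  Ties break to the lowest legend code.  Cells
    with no coverage get the blank sentinel.
    """
    if not polygons:
        raise ValueError("polygon list is empty")
    if attribute not in ("community", "species"):
        raise ValueError(f"unknown attribute {attribute!r}")

    labels = [getattr(p, attribute) for p in polygons]
    legend = build_legend(labels)
    code_of = {v: k for k, v in legend.items()}

    coverage: dict[int, np.ndarray] = {}
    x0, y0 = grid.origin
    s = grid.cell_size
    for poly, label in zip(polygons, labels):
        geom = poly.geometry
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(0, int(np.floor((minx - x0) / s)))
        c1 = min(grid.width, int(np.ceil((maxx - x0) / s)))
        r0 = max(0, int(np.floor((y0 - maxy) / s)))
        r1 = min(grid.height, int(np.ceil((y0 - miny) / s)))
        if c0 >= c1 or r0 >= r1:
            continue
        rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        boxes = _cell_boxes(grid, rows.ravel(), cols.ravel())
        areas = shapely.area(shapely.intersection(boxes, geom))
        code = code_of[label if label else ""]
        cov = coverage.setdefault(code, np.zeros((grid.height, grid.width)))
        cov[rows.ravel(), cols.ravel()] += areas

    best_area = np.zeros((grid.height, grid.width))
    out = np.full((grid.height, grid.width), BLANK, dtype=np.int32)
    eps = 1e-9 * s * s
    for code in sorted(coverage):  # ascending code order => lowest code wins ties
        cov = coverage[code]
        take = cov > best_area + eps
        out[take] = code
        best_area = np.maximum(best_area, cov)
    out[best_area <= eps] = BLANK
    return CategoricalRaster(grid=grid, codes=out, legend=legend)


def vectorize(raster: CategoricalRaster, attribute: str = "community") -> list[AttributedPolygon]:
    """One merged polygon per non-blank raster class (inverse of rasterization)."""
    out = []
    for code in sorted(np.unique(raster.codes).tolist()):
        if code == BLANK:
            continue
        rows, cols = np.nonzero(raster.codes == code)
        geom = shapely.union_all(_cell_boxes(raster.grid, rows, cols))
        label = raster.legend[code]
        attrs = {attribute: label}
        out.append(AttributedPolygon(geometry=geom, **attrs))
    return out


def geometric_union(
    community_polys: list[AttributedPolygon], species_polys: list[AttributedPolygon]
) -> list[AttributedPolygon]:
    """Overlay community and species layers into (community, species) pieces.

    The output partitions the union of both inputs: overlapping parts carry
    both labels, parts covered by only one layer carry that label and a blank
    for the other.  Total area is conserved (layers are assumed internally
    non-overlapping, as community maps and majority-rasterized species maps
    are).
    """
    def _clean(g):
        return g if g.is_valid else shapely.make_valid(g)

    comm = [(p.community, _clean(p.geometry)) for p in community_polys]
    spec = [(p.species, _clean(p.geometry)) for p in species_polys]
    comm_union = shapely.union_all([g for _, g in comm]) if comm else Polygon()
    spec_union = shapely.union_all([g for _, g in spec]) if spec else Polygon()

    pieces: list[AttributedPolygon] = []

    def _add(geom, community, species):
        if geom.is_empty:
            return
        for part in getattr(geom, "geoms", [geom]):
            if part.area > 1e-9:
                pieces.append(
                    AttributedPolygon(geometry=part, community=community, species=species)
                )

    for c_label, c_geom in comm:
        _add(c_geom.difference(spec_union), c_label, "")
        for s_label, s_geom in spec:
            _add(c_geom.intersection(s_geom), c_label, s_label)
    for s_label, s_geom in spec:
        _add(s_geom.difference(comm_union), "", s_label)
    return pieces


def crown_centroid(polygon: Polygon) -> Point:
    """Area centroid of a crown polygon (the tree's assumed trunk location)."""
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("cannot take the centroid of a zero-area geometry")
    return polygon.centroid


def canopy_area(landcover: CategoricalRaster) -> float:
    """Canopy-bearing area in ha: everything except runway, bare ground,
    grassland, unknown, water and blank cells."""
    excluded = CANOPY_EXCLUDED | {WATER, BLANK}
    included = ~np.isin(landcover.codes, list(excluded))
    return float(included.sum()) * landcover.grid.cell_area_ha


# ---------------------------------------------------------------------------
# text-based I/O: ESRI ASCII grids, CSV legends, GeoJSON vectors
# ---------------------------------------------------------------------------

def write_ascii_grid(path, raster_or_elev) -> None:
    if isinstance(raster_or_elev, CategoricalRaster):
        grid, data, nodata = raster_or_elev.grid, raster_or_elev.codes, -9999
        fmt = "%d"
    else:
        grid = raster_or_elev.grid
        data = np.where(raster_or_elev.nodata, -9999.0, raster_or_elev.values)
        nodata, fmt = -9999, "%.3f"
    x0, y0 = grid.origin
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.width}\nnrows {grid.height}\n")
        fh.write(f"xllcorner {x0}\nyllcorner {y0 - grid.height * grid.cell_size}\n")
        fh.write(f"cellsize {grid.cell_size}\nNODATA_value {nodata}\n")
        np.savetxt(fh, data, fmt=fmt)


def write_legend_csv(path, legend: dict[int, str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "label"])
        for code in sorted(legend):
            w.writerow([code, legend[code]])


def read_legend_csv(path) -> dict[int, str]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return {int(r["code"]): r["label"] for r in rows}


def write_geojson(path, geometries, properties=None) -> None:
    features = []
    for i, geom in enumerate(geometries):
        props = properties[i] if properties else {}
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path):
    with open(path) as fh:
        fc = json.load(fh)
    return [(shape(f["geometry"]), f.get("properties", {})) for f in fc["features"]]
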