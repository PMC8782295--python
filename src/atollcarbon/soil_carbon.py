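"""Soil organic-carbon stock estimation over a 20 cm accounting depth.

Two estimators share one stock formula:

* **Random-forest method** — sample %C values are binned low (<10%), medium
  (10-20%) and high (>20%); a random forest over the two categorical
  predictors (vegetation community, tree species) predicts a bin per raster
  cell; bin mean %C and bin mean dry bulk density feed the stock formula.
* **Averages method** — the community x species union polygons receive mean
  %C and bulk density through a fallback ladder: combination mean (n >= 2),
  else community mean, else species mean, else the global sample mean; zero
  where either label is blank, unknown, water, or runway.

Stock formula (unit-exact, g cm^-3 == Mg m^-3):

    Mg C = (%C / 100) * bulk_density * depth * area_ha * 100
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import OneHotEncoder

from .spatial_core import (
    BLANK,
    RUNWAY,
    UNKNOWN,
    WATER,
    AttributedPolygon,
    CategoricalRaster,
)

logger = logging.getLogger(__name__)

BIN_LOW, BIN_MEDIUM, BIN_HIGH = "low", "medium", "high"
BIN_ORDER = (BIN_LOW, BIN_MEDIUM, BIN_HIGH)
LOW_THRESHOLD, HIGH_THRESHOLD = 10.0, 20.0

#: labels that zero out a polygon or cell in either method
ZERO_LABELS = frozenset({"", "water", "unknown", "runway"})
_ZERO_CODES = (BLANK, WATER, UNKNOWN, RUNWAY)


@dataclass
class SoilSample:
    site_id: str
    islet: str
    year: int
    community: str
    species: str
    total_c_pct: float
    organic_c_pct: float | None
    bulk_density: float
    hardpan_depth_cm: float | None = None
    location: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.total_c_pct <= 100:
            raise ValueError("total %C must lie in [0, 100]")
        if self.organic_c_pct is not None and not 0 <= self.organic_c_pct <= 100:
            raise ValueError("organic %C must lie in [0, 100]")
        if self.bulk_density <= 0:
            raise ValueError("bulk density must be positive")


@dataclass(frozen=True)
class StockParams:
    depth_cm: float = 20.0  # accounting depth, from mean hardpan depth
    carbon_fraction_of_pct: float = 0.01  # %C -> mass fraction

    def __post_init__(self) -> None:
        if self.depth_cm <= 0:
            raise ValueError("depth must be positive")


@dataclass
class OCRegression:
    """OLS of organic %C on total %C, used to impute organic values."""

    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class BinScheme:
    """Per-bin sample statistics (the calibration behind both estimators)."""

    stats: pd.DataFrame  # index: bin; columns n, c_pct_mean, c_pct_se, bd_mean, bd_se

    def mean_c_pct(self, bin_label: str) -> float:
        return float(self.stats.loc[bin_label, "c_pct_mean"])

    def mean_bd(self, bin_label: str) -> float:
        return float(self.stats.loc[bin_label, "bd_mean"])


def assign_bin(organic_c_pct: float) -> str:
    """low (<10), medium (10-20 inclusive), high (>20)."""
    if not 0 <= organic_c_pct <= 100:
        raise ValueError("%C out of [0, 100]")
    if organic_c_pct < LOW_THRESHOLD:
        return BIN_LOW
    if organic_c_pct <= HIGH_THRESHOLD:
        return BIN_MEDIUM
    return BIN_HIGH


def fit_oc_regression(samples: list[SoilSample]) -> OCRegression:
    """Fit organic ~ total %C on samples having both measurements."""
    pairs = [
        (s.total_c_pct, s.organic_c_pct)
        for s in samples
        if s.organic_c_pct is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (total, organic) pairs to fit")
    x, y = map(np.asarray, zip(*pairs))
    res = stats.linregress(x, y)
    return OCRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(pairs),
    )


def impute_organic(samples: list[SoilSample], reg: OCRegression) -> list[SoilSample]:
    """Fill missing organic %C as slope*total + intercept, clamped to [0, total]."""
    for s in samples:
        if s.organic_c_pct is None:
            pred = reg.slope * s.total_c_pct + reg.intercept
            s.organic_c_pct = float(np.clip(pred, 0.0, s.total_c_pct))
    return samples


def fit_bin_stats(samples: list[SoilSample]) -> BinScheme:
    """Count, mean %C, mean bulk density and SEs per occupied bin."""
    rows = []
    df = pd.DataFrame(
        {
            "bin": [assign_bin(s.organic_c_pct) for s in samples],
            "c_pct": [s.organic_c_pct for s in samples],
            "bd": [s.bulk_density for s in samples],
        }
    )
    for b in BIN_ORDER:
        sub = df[df["bin"] == b]
        if sub.empty:
            continue
        n = len(sub)
        rows.append(
            {
                "bin": b,
                "n": n,
                "c_pct_mean": sub["c_pct"].mean(),
                "c_pct_se": sub["c_pct"].sem() if n > 1 else np.nan,
                "bd_mean": sub["bd"].mean(),
                "bd_se": sub["bd"].sem() if n > 1 else np.nan,
            }
        )
    return BinScheme(stats=pd.DataFrame(rows).set_index("bin"))


class BinClassifier:
    """Random forest mapping (community, species) labels to a soil-carbon bin.

    The two categorical predictors are one-hot encoded; 500 trees with a
    fixed seed make predictions reproducible.  Out-of-bag accuracy is kept
    as a fit diagnostic.
    """

    def __init__(self, n_trees: int = 500, seed: int = 0):
        self.n_trees = n_trees
        self.seed = seed
        self.encoder: OneHotEncoder | None = None
        self.forest: RandomForestClassifier | None = None
        self.oob_accuracy: float | None = None
        self.constant_class: str | None = None

    def fit(self, samples: list[SoilSample]) -> "BinClassifier":
        X = [[s.community, s.species] for s in samples]
        y = [assign_bin(s.organic_c_pct) for s in samples]
        if len(set(y)) < 2:
            warnings.warn("single-class training data; using a constant classifier")
            self.constant_class = y[0]
            return self
        self.encoder = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        Xe = self.encoder.fit_transform(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # OOB estimate noisy at small n
            self.forest = RandomForestClassifier(
                n_estimators=self.n_trees,
                oob_score=True,
                random_state=self.seed,
                bootstrap=True,
            ).fit(Xe, y)
        try:
            self.oob_accuracy = float(self.forest.oob_score_)
        except AttributeError:  # pragma: no cover
            self.oob_accuracy = None
        return self

    def predict(self, labels: list[tuple[str, str]]) -> list[str]:
        if self.constant_class is not None:
            return [self.constant_class] * len(labels)
        if self.forest is None:
            raise ValueError("classifier is not fitted")
        Xe = self.encoder.transform([list(t) for t in labels])
        return list(self.forest.predict(Xe))


def fit_bin_classifier(samples: list[SoilSample], seed: int = 0, n_trees: int = 500) -> BinClassifier:
    return BinClassifier(n_trees=n_trees, seed=seed).fit(samples)


def stock_formula(c_pct: float, bulk_density: float, depth_cm: float, area_ha: float) -> float:
    """Soil carbon stock in Mg C.

    (c_pct/100) [Mg C / Mg soil] x bulk_density [Mg m^-3] x depth [m]
    x area [m^2] collapses to ``c_pct/100 * bd * depth_cm * area_ha * 100``.
    """
    if min(c_pct, bulk_density, depth_cm, area_ha) < 0:
        raise ValueError("stock_formula arguments must be non-negative")
    return (c_pct / 100.0) * bulk_density * depth_cm * area_ha * 100.0


def predict_soil_map(
    classifier: BinClassifier,
    community_raster: CategoricalRaster,
    species_raster: CategoricalRaster,
    bins: BinScheme,
    params: StockParams = StockParams(),
) -> tuple[np.ndarray, float]:
    """Per-cell soil-carbon density (Mg C ha^-1) and the summed total (Mg C).

    Prediction runs once per distinct (community, species) label pair and is
    broadcast to cells; sentinel cells (blank/water/unknown/runway on either
    layer) contribute zero.
    """
    if community_raster.grid != species_raster.grid:
        raise ValueError("community and species rasters must share a grid")
    comm, spec = community_raster.codes, species_raster.codes
    zero = np.isin(comm, _ZERO_CODES) | np.isin(spec, _ZERO_CODES)

    pair_codes = comm.astype(np.int64) * 100_000 + spec.astype(np.int64)
    unique_pairs, inverse = np.unique(pair_codes, return_inverse=True)
    labels = [
        (community_raster.legend[int(p // 100_000)], species_raster.legend[int(p % 100_000)])
        for p in unique_pairs
    ]
    predicted = classifier.predict(labels)
    density_per_pair = np.array(
        [
            stock_formula(bins.mean_c_pct(b), bins.mean_bd(b), params.depth_cm, 1.0)
            for b in predicted
        ]
    )
    density = density_per_pair[inverse].reshape(comm.shape)
    density[zero] = 0.0
    total = float(density.sum()) * community_raster.grid.cell_area_ha
    return density, total


def _fallback_table(samples: list[SoilSample]) -> dict:
    """Means behind the averages-method fallback ladder."""
    df = pd.DataFrame(
        {
            "community": [s.community for s in samples],
            "species": [s.species for s in samples],
            "c_pct": [s.organic_c_pct for s in samples],
            "bd": [s.bulk_density for s in samples],
        }
    )
    combo = df.groupby(["community", "species"]).agg(
        n=("c_pct", "size"), c_pct=("c_pct", "mean"), bd=("bd", "mean")
    )
    return {
        "combo": combo,
        "community": df.groupby("community")[["c_pct", "bd"]].mean(),
        "species": df.groupby("species")[["c_pct", "bd"]].mean(),
        "global": df[["c_pct", "bd"]].mean(),
    }


def _lookup_means(table: dict, community: str, species: str) -> tuple[float, float]:
    combo = table["combo"]
    if (community, species) in combo.index and combo.loc[(community, species), "n"] >= 2:
        row = combo.loc[(community, species)]
        return float(row["c_pct"]), float(row["bd"])
    if community in table["community"].index:
        row = table["community"].loc[community]
        return float(row["c_pct"]), float(row["bd"])
    if species in table["species"].index:
        row = table["species"].loc[species]
        return float(row["c_pct"]), float(row["bd"])
    g = table["global"]
    return float(g["c_pct"]), float(g["bd"])


def averages_method(
    union_polys: list[AttributedPolygon],
    samples: list[SoilSample],
    params: StockParams = StockParams(),
) -> tuple[pd.DataFrame, float]:
    """Averages-method soil stocks over community x species union polygons.

    Returns a per-polygon table (labels, area, assigned means, stock) and the
    total stock in Mg C.  Polygons whose community or species label is blank,
    unknown, water, or runway contribute zero.
    """
    if not samples:
        raise ValueError("averages method needs at least one sample")
    table = _fallback_table(samples)
    rows = []
    for p in union_polys:
        if p.community.lower() in ZERO_LABELS or p.species.lower() in ZERO_LABELS:
            c_pct, bd, stock = 0.0, 0.0, 0.0
        else:
            c_pct, bd = _lookup_means(table, p.community, p.species)
            stock = stock_formula(c_pct, bd, params.depth_cm, p.area_ha)
        rows.append(
            {
                "community": p.community,
                "species": p.species,
                "area_ha": p.area_ha,
                "c_pct": c_pct,
                "bulk_density": bd,
                "stock_mg_c": stock,
            }
        )
    df = pd.DataFrame(rows)
    return df, float(df["stock_mg_c"].sum())


def averages_method_rasters(
    community_raster: CategoricalRaster,
    species_raster: CategoricalRaster,
    samples: list[SoilSample],
    params: StockParams = StockParams(),
) -> tuple[pd.DataFrame, float]:
    """Raster-native averages method: the union overlay reduces to a
    cross-tabulation of (community, species) cell counts, which is what the
    polygon union measures."""
    if not samples:
        raise ValueError("averages method needs at least one sample")
    comm, spec = community_raster.codes, species_raster.codes
    pair_codes = comm.astype(np.int64) * 100_000 + spec.astype(np.int64)
    unique_pairs, counts = np.unique(pair_codes, return_counts=True)
    cell_ha = community_raster.grid.cell_area_ha
    table = _fallback_table(samples)
    rows = []
    for p, n in zip(unique_pairs, counts):
        community = community_raster.legend[int(p // 100_000)]
        species = species_raster.legend[int(p % 100_000)]
        area_ha = float(n) * cell_ha
        if community.lower() in ZERO_LABELS or species.lower() in ZERO_LABELS:
            c_pct, bd, stock = 0.0, 0.0, 0.0
        else:
            c_pct, bd = _lookup_means(table, community, species)
            stock = stock_formula(c_pct, bd, params.depth_cm, area_ha)
        rows.append(
            {
                "community": community,
                "species": species,
                "area_ha": area_ha,
                "c_pct": c_pct,
                "bulk_density": bd,
                "stock_mg_c": stock,
            }
        )
    df = pd.DataFrame(rows)
    return df, float(df["stock_mg_c"].sum())


def compare_methods(rf_total: float, averages_total: float) -> dict:
    """Discrepancy report between the two estimators on the same scene."""
    diff = averages_total - rf_total
    denom = max(abs(rf_total), abs(averages_total))
    rel = abs(diff) / denom if denom > 0 else 0.0
    return {
        "random_forest_mg_c": rf_total,
        "averages_mg_c": averages_total,
        "abs_difference_mg_c": abs(diff),
        "rel_difference": rel,
        "more_conservative": "random_forest" if rf_total <= averages_total else "averages",
    }
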