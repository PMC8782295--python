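"""One-call pipeline runner and published-table replication checks.

``run_pipeline`` ties every stage together on a synthetic scene: generation,
soil-carbon estimation by both methods, per-tree aboveground accounting, the
transformation scenario, chronosequence accumulation projections, and the
nearshore DOC comparison.  All randomness flows from the run seed; outputs
can be written to disk with a manifest (config hash, seed, versions), and
additive tables are conservation-checked before they are returned.

``replicate_tables`` recomputes the derived cells of the published carbon
accounting (scenario totals and percent changes; 15-year accumulation column
sums) from their printed component values and reports any mismatch at the
printed 1-decimal rounding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import reference
from .aboveground_carbon import (
    AllometryParams,
    aboveground_totals,
    account_trees,
    quadratic_mean_diameter,
)
from .accumulation import (
    AccumulationEntry,
    chronosequence_rate,
    project_accumulation,
    scenario_delta,
)
from .doc_runoff import canopy_effect, comparison_summary, exclude_managed, pool_intertidal
from .scenario import (
    ScenarioSummary,
    TransformationPlan,
    reassign_crowns,
    reassign_species_raster,
    reclassify_communities,
    scenario_summary,
)
from .soil_carbon import (
    StockParams,
    averages_method_rasters,
    compare_methods,
    fit_bin_classifier,
    fit_bin_stats,
    fit_oc_regression,
    impute_organic,
    predict_soil_map,
)
from .spatial_core import canopy_area, write_ascii_grid, write_legend_csv
from .synthetic_atoll import (
    DOCTruth,
    SceneConfig,
    SoilTruth,
    generate_scene,
    sample_doc,
    sample_soil,
    true_soil_total_mg,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    soil_truth: SoilTruth = field(default_factory=SoilTruth)
    doc_truth: DOCTruth = field(default_factory=DOCTruth)
    soil_method: str = "both"  # random_forest | averages | both
    n_soil_sites: int = reference.TOTAL_SOIL_SITES
    n_doc_sites: int = reference.DOC_N_SITES
    stock_params: StockParams = field(default_factory=StockParams)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    horizon_years: int = reference.ACCUMULATION_HORIZON_YEARS
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.soil_method not in ("random_forest", "averages", "both"):
            raise ValueError("soil_method must be random_forest, averages, or both")


@dataclass
class CarbonReport:
    bin_stats: pd.DataFrame
    scenario: ScenarioSummary
    per_islet: pd.DataFrame
    per_species: pd.DataFrame
    accumulation_no_transform: pd.DataFrame
    accumulation_transform: pd.DataFrame
    accumulation_delta: dict
    doc: dict
    method_comparison: dict | None
    truth_recovery: dict
    manifest: dict


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(asdict_safe(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(obj):
    try:
        return asdict(obj)
    except TypeError:
        return str(obj)


def _islet_index(scene) -> np.ndarray:
    xs, ys = scene.grid.cell_centers()
    flat_x, flat_y = xs.ravel(), ys.ravel()
    idx = np.full(flat_x.size, -1, dtype=np.int32)
    for i, (_, poly, _) in enumerate(scene.islets):
        idx[shapely.contains_xy(poly, flat_x, flat_y)] = i
    return idx.reshape(xs.shape)


def _per_islet_table(scene, soil_density, future_density, crowns, future_crowns) -> pd.DataFrame:
    idx = _islet_index(scene)
    cell_ha = scene.grid.cell_area_ha
    rows = []
    for i, (name, poly, area) in enumerate(scene.islets):
        mask = idx == i
        soil_pre = float(soil_density[mask].sum()) * cell_ha
        soil_post = float(future_density[mask].sum()) * cell_ha
        ab_pre = sum(
            (t.carbon or 0.0) for t in crowns if poly.contains(t.centroid)
        ) / 1000.0
        ab_post = sum(
            (t.carbon or 0.0) for t in future_crowns if poly.contains(t.centroid)
        ) / 1000.0
        rows.append(
            {
                "islet": name, "area_ha": area,
                "soil_pre_mg_c": soil_pre, "soil_post_mg_c": soil_post,
                "aboveground_pre_mg_c": ab_pre, "aboveground_post_mg_c": ab_post,
                "total_pre_mg_c": soil_pre + ab_pre,
                "total_post_mg_c": soil_post + ab_post,
            }
        )
    df = pd.DataFrame(rows)
    total = df.drop(columns=["islet"]).sum()
    total["islet"] = "TOTAL"
    return pd.concat([df, total.to_frame().T], ignore_index=True)


def run_pipeline(config: RunConfig) -> CarbonReport:
    """Execute every stage on one synthetic scene; deterministic per seed."""
    scene_cfg = config.scene
    if scene_cfg.seed != config.seed:
        scene_cfg = SceneConfig(**{**scene_cfg.__dict__, "seed": config.seed})
    scene, truth = generate_scene(scene_cfg)
    logger.info(
        "scene: %d islets, %d crowns, canopy %.1f ha",
        len(scene.islets), len(scene.crowns), truth.canopy_area_ha,
    )

    # --- soil calibration -------------------------------------------------
    samples = sample_soil(scene, config.soil_truth, config.n_soil_sites, seed=config.seed)
    reg = fit_oc_regression(samples)
    samples = impute_organic(samples, reg)
    bins = fit_bin_stats(samples)
    clf = fit_bin_classifier(samples, seed=config.seed)

    # --- baseline stocks --------------------------------------------------
    sp_means = scene_cfg.species_height_means
    qmd = {
        sp: quadratic_mean_diameter(d) for sp, d in truth.transect_diameters.items()
    }
    canopy_ha = canopy_area(scene.landcover)

    soil_density, soil_total_rf = predict_soil_map(
        clf, scene.community_raster, scene.species_raster, bins, config.stock_params
    )
    _, soil_total_avg = averages_method_rasters(
        scene.community_raster, scene.species_raster, samples, config.stock_params
    )

    crowns = account_trees(
        scene.crowns, scene.elevation, sp_means, qmd, params=config.allometry
    )
    ab_table = aboveground_totals(crowns, canopy_ha)
    ab_total = float(ab_table.loc["TOTAL", "total_mg_c"])

    # --- transformation scenario -----------------------------------------
    plan = TransformationPlan(polygons=truth.transformation_polygons, seed=config.seed)
    future_comm = reclassify_communities(scene.community_raster, plan)
    future_spec = reassign_species_raster(scene.species_raster, plan)
    future_crowns = reassign_crowns(
        crowns, plan, sp_means, qmd, reference.BWD_MEANS
    )
    future_crowns = account_trees(
        future_crowns, scene.elevation, sp_means, qmd, params=config.allometry
    )
    n_reassigned = sum(
        1 for a, b in zip(crowns, future_crowns) if a.species != b.species
    )
    logger.info("scenario: %d crowns reassigned", n_reassigned)

    future_density, future_soil_rf = predict_soil_map(
        clf, future_comm, future_spec, bins, config.stock_params
    )
    _, future_soil_avg = averages_method_rasters(
        future_comm, future_spec, samples, config.stock_params
    )
    future_ab_table = aboveground_totals(future_crowns, canopy_ha)
    future_ab_total = float(future_ab_table.loc["TOTAL", "total_mg_c"])

    if config.soil_method == "averages":
        soil_total, future_soil = soil_total_avg, future_soil_avg
    else:  # random forest is the headline (more conservative) estimator
        soil_total, future_soil = soil_total_rf, future_soil_rf
    comparison = (
        {
            "baseline": compare_methods(soil_total_rf, soil_total_avg),
            "future": compare_methods(future_soil_rf, future_soil_avg),
        }
        if config.soil_method == "both"
        else None
    )

    summary = scenario_summary(
        ab_total, soil_total, future_ab_total, future_soil,
        canopy_ha, canopy_area(scene.landcover),
    )

    # --- accumulation projections ----------------------------------------
    cell_ha = scene.grid.cell_area_ha
    ages = reference.CHRONOSEQUENCE["islet_ages"]
    lit = reference.CHRONOSEQUENCE["c_nucifera_literature"]

    def _class_area(raster, label):
        code = {v: k for k, v in raster.legend.items()}.get(label)
        return float((raster.codes == code).sum()) * cell_ha if code is not None else 0.0

    def _class_density(label):
        code = {v: k for k, v in scene.community_raster.legend.items()}.get(label)
        if code is None:
            return 0.0
        mask = scene.community_raster.codes == code
        return float(soil_density[mask].mean()) if mask.any() else 0.0

    entries = [
        AccumulationEntry(
            community="C. nucifera",
            area_current_ha=_class_area(scene.community_raster, "C. nucifera"),
            area_projected_ha=_class_area(future_comm, "C. nucifera"),
            rate=chronosequence_rate(lit["stock_per_ha"], lit["age"]),
            rate_source="literature",
            horizon_years=config.horizon_years,
        ),
        AccumulationEntry(
            community="P. grandis/H. foertherianum",
            area_current_ha=_class_area(scene.community_raster, "P. grandis/H. foertherianum"),
            area_projected_ha=_class_area(future_comm, "P. grandis/H. foertherianum"),
            rate=chronosequence_rate(
                _class_density("P. grandis/H. foertherianum"), ages["Dudley/Lesley"]
            ),
            horizon_years=config.horizon_years,
        ),
        AccumulationEntry(
            community="C. nucifera/H. foertherianum",
            area_current_ha=_class_area(scene.community_raster, "C. nucifera/H. foertherianum"),
            area_projected_ha=_class_area(future_comm, "C. nucifera/H. foertherianum"),
            rate=chronosequence_rate(
                _class_density("C. nucifera/H. foertherianum"), ages["N. Fighter"]
            ),
            horizon_years=config.horizon_years,
        ),
    ]
    acc_no = project_accumulation(entries, "no_transform")
    acc_tr = project_accumulation(entries, "transform")
    delta = scenario_delta(
        float(acc_no.iloc[-1]["accumulation_mg_c"]),
        float(acc_tr.iloc[-1]["accumulation_mg_c"]),
    )

    # --- DOC comparison ---------------------------------------------------
    doc_samples = sample_doc(scene, config.doc_truth, config.n_doc_sites, seed=config.seed)
    pooled, pool_report = pool_intertidal(doc_samples)
    kept, excluded = exclude_managed(pooled)
    doc_result = canopy_effect(kept, seed=config.seed)
    doc_result["pooling"] = pool_report
    doc_result["n_excluded_samples"] = len(excluded)
    doc_result["habitat_summary"] = comparison_summary(kept)

    # --- bookkeeping tables and invariants --------------------------------
    per_islet = _per_islet_table(scene, soil_density, future_density, crowns, future_crowns)
    per_species = pd.concat(
        {"baseline": ab_table, "future": future_ab_table}, axis=1
    )

    grand = per_islet[per_islet["islet"] == "TOTAL"].iloc[0]
    if not np.isclose(grand["soil_pre_mg_c"], soil_total_rf, rtol=1e-6):
        raise AssertionError("per-islet soil totals do not sum to the grand total")
    if not np.isclose(grand["aboveground_pre_mg_c"], ab_total, rtol=1e-6):
        raise AssertionError("per-islet aboveground totals do not sum to the grand total")
    if float(ab_table.loc["TOTAL", "total_mg_c"]) > grand["total_pre_mg_c"] + 1e-6:
        raise AssertionError("per-species total exceeds grand total")

    recovery = {
        "true_soil_mg_c": true_soil_total_mg(scene, config.soil_truth, config.stock_params),
        "true_aboveground_mg_c": truth.true_aboveground_total_mg(params=config.allometry),
        "estimated_soil_rf_mg_c": soil_total_rf,
        "estimated_soil_avg_mg_c": soil_total_avg,
        "estimated_aboveground_mg_c": ab_total,
    }

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_crowns": len(crowns),
        "n_crowns_reassigned": n_reassigned,
        "n_soil_samples": len(samples),
        "n_doc_samples": len(doc_samples),
        "oob_accuracy": clf.oob_accuracy,
        "oc_regression": {"slope": reg.slope, "intercept": reg.intercept, "r2": reg.r_squared},
        "versions": _versions(),
    }

    report = CarbonReport(
        bin_stats=bins.stats,
        scenario=summary,
        per_islet=per_islet,
        per_species=per_species,
        accumulation_no_transform=acc_no,
        accumulation_transform=acc_tr,
        accumulation_delta=delta,
        doc=doc_result,
        method_comparison=comparison,
        truth_recovery=recovery,
        manifest=manifest,
    )
    if config.output_dir:
        _write_report(Path(config.output_dir), report, scene, soil_density, future_density)
    return report


def _versions() -> dict:
    import sklearn
    import numpy
    import pandas
    import shapely as shp

    return {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "shapely": shp.__version__,
    }


def _write_report(outdir: Path, report: CarbonReport, scene, soil_density, future_density) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.bin_stats.to_csv(outdir / "bin_stats.csv")
    report.per_islet.to_csv(outdir / "per_islet.csv", index=False)
    report.per_species.to_csv(outdir / "per_species.csv")
    report.accumulation_no_transform.to_csv(outdir / "accumulation_no_transform.csv", index=False)
    report.accumulation_transform.to_csv(outdir / "accumulation_transform.csv", index=False)
    summary = {
        "canopy_area_ha": report.scenario.canopy_area_ha,
        "baseline": report.scenario.baseline,
        "future": report.scenario.future,
        "pct_change": report.scenario.pct_change,
        "accumulation_delta": report.accumulation_delta,
        "doc": {
            k: v for k, v in report.doc.items()
            if isinstance(v, (int, float, str, dict)) and k != "habitat_summary"
        },
        "truth_recovery": report.truth_recovery,
        "manifest": report.manifest,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    from .spatial_core import CategoricalRaster, ElevationSurface

    write_ascii_grid(outdir / "community.asc", scene.community_raster)
    write_legend_csv(outdir / "community_legend.csv", scene.community_raster.legend)
    write_ascii_grid(
        outdir / "soil_density_pre.asc",
        ElevationSurface(scene.grid, soil_density, np.zeros_like(soil_density, dtype=bool)),
    )
    write_ascii_grid(
        outdir / "soil_density_post.asc",
        ElevationSurface(scene.grid, future_density, np.zeros_like(future_density, dtype=bool)),
    )


# ---------------------------------------------------------------------------
# published-table replication
# ---------------------------------------------------------------------------

def replicate_tables() -> dict:
    """Recompute derived accounting cells from printed components.

    Scenario summary: component totals give the grand totals and percent
    changes.  Accumulation: per-community cells give the two column sums.
    Sample bookkeeping: per-islet counts give the study site total.  Each
    recomputed value is compared with its printed counterpart at 1-decimal
    rounding; mismatches are listed with both values.
    """
    comp = reference.CARBON_SUMMARY_COMPONENTS
    derived = reference.CARBON_SUMMARY_DERIVED
    from .scenario import percent_change as pct

    checks = []

    def check(name, computed, printed, nd=1):
        ok = round(computed, nd) == round(printed, nd)
        checks.append({"cell": name, "computed": round(computed, nd), "printed": printed, "ok": ok})

    base_total = comp["aboveground"]["baseline_total"] + comp["soil"]["baseline_total"]
    fut_total = comp["aboveground"]["future_total"] + comp["soil"]["future_total"]
    check("scenario_baseline_total", base_total, derived["baseline_total"])
    check("scenario_future_total", fut_total, derived["future_total"])
    check(
        "pct_change_aboveground",
        pct(comp["aboveground"]["baseline_total"], comp["aboveground"]["future_total"]),
        derived["pct_change"]["aboveground"],
    )
    check(
        "pct_change_soil",
        pct(comp["soil"]["baseline_total"], comp["soil"]["future_total"]),
        derived["pct_change"]["soil"],
    )
    check("pct_change_total", pct(base_total, fut_total), derived["pct_change"]["total"])

    acc = reference.ACCUMULATION_TABLE
    no_tr = sum(row[2] for row in acc.values())
    tr = sum(row[4] for row in acc.values())
    check("accumulation_no_transform_total", no_tr, reference.ACCUMULATION_TOTALS["no_transform"])
    check("accumulation_transform_total", tr, reference.ACCUMULATION_TOTALS["transform"])

    n_sites = sum(n for n, _ in reference.SOIL_SAMPLES_BY_ISLET.values())
    check("soil_site_count", float(n_sites), float(reference.TOTAL_SOIL_SITES), nd=0)

    mismatches = [c for c in checks if not c["ok"]]
    return {"checks": checks, "mismatches": mismatches, "ok": not mismatches}
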