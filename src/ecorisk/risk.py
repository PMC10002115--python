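"""Risk synthesis and pipeline orchestration.

Risk = Hazard x Vulnerability x Damage, cell-wise on the hazard grid, with the
coarse vulnerability surface upsampled by nearest-cell assignment so each fine
cell inherits its analysis cell's VI.  The product is classified into five
levels by natural breaks and reported with per-class area percentages and a
disaster frequency table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .damage import (
    c_factor,
    ls_factor,
    p_factor,
    potential_damage,
    runoff_from_landcover,
    rusle,
    water_conservation,
)
from .geodata import (
    FrequencyTable,
    classify,
    frequency_table,
    jenks_breaks_raster,
    resample_to_grid,
)
from .grid import ClassifiedMap, Raster, stack_grids, union_nodata
from .hazard import (
    DisasterInventory,
    HazardModelConfig,
    SampleSet,
    extract_features,
    information_value_map,
    predict_hazard,
    roc_auc,
    sample_negatives,
    split_inventory,
    tune_and_fit,
)
from .synthetic import PlantedHazardModel, RegionConfig, SyntheticRegion, generate_region
from .vulnerability import vulnerability_map

__all__ = ["RiskLayers", "compose_risk", "risk_report", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger("ecorisk")


@dataclass
class RiskLayers:
    """The three risk components, their product, and its classification."""

    hazard: Raster
    vulnerability: Raster
    damage: Raster
    risk: Raster
    classified_risk: ClassifiedMap | None
    class_area_pct: dict[int, float]


def _check_unit_interval(raster: Raster, name: str) -> None:
    vals = raster.unmasked()
    if vals.size == 0:
        raise ValueError(f"component {name!r} has no unmasked cells")
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    if lo < -1e-12 or hi > 1.0 + 1e-12:
        raise ValueError(f"component {name!r} outside [0, 1]: min {lo:g}, max {hi:g}")


def compose_risk(
    hazard: Raster,
    vulnerability: Raster,
    damage: Raster,
    jenks_seed: int = 0,
) -> RiskLayers:
    """Cell-wise product of the three [0, 1] components on the hazard grid.

    A vulnerability raster on a coarser analysis grid is upsampled by nearest-
    cell assignment first.  The union of nodata masks applies; the product is
    classified into five natural-breaks levels and per-class area percentages
    are reported.
    """
    if vulnerability.grid != hazard.grid:
        vulnerability = resample_to_grid(vulnerability, hazard.grid, method="nearest")
    stack_grids(hazard, vulnerability, damage)
    for r, n in ((hazard, "hazard"), (vulnerability, "vulnerability"), (damage, "damage")):
        _check_unit_interval(r, n)
    mask = union_nodata(hazard, vulnerability, damage)
    product = hazard.values * vulnerability.values * damage.values
    risk = Raster(hazard.grid, product, mask)

    vals = risk.unmasked()
    if np.unique(vals).size >= 5:
        classified = classify(risk, jenks_breaks_raster(risk, k=5, seed=jenks_seed))
        counts = np.bincount(classified.raster.codes[~mask], minlength=6)[1:6]
        total = counts.sum()
        class_area_pct = {i + 1: round(100.0 * c / total, 2) for i, c in enumerate(counts)}
    else:
        classified = None
        class_area_pct = {1: 100.0}
    return RiskLayers(hazard, vulnerability, damage, risk, classified, class_area_pct)


def risk_report(
    layers: RiskLayers,
    inventory: DisasterInventory | None = None,
    raster_paths: dict[str, str] | None = None,
    config_echo: dict | None = None,
) -> dict:
    """Machine-readable report: class area shares, disaster frequencies per
    risk class, emitted raster paths, and the full config echo."""
    report: dict = {"class_area_pct": layers.class_area_pct}
    if layers.classified_risk is not None and inventory is not None:
        table = frequency_table(layers.classified_risk, inventory.coords)
        report["frequency_table"] = table.to_frame().to_dict(orient="records")
    if raster_paths:
        report["rasters"] = dict(raster_paths)
    if config_echo:
        report["config"] = config_echo
    return report


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    region: RegionConfig = field(default_factory=RegionConfig)
    planted: PlantedHazardModel = field(default_factory=PlantedHazardModel)
    model: str = "rf"  # "rf" | "iv"
    train_fraction: float = 0.7
    # exclusion buffer around disaster points when drawing negatives.  The
    # 500 m operating default of sample_negatives suits province-scale
    # inventories; on the compact synthetic region (~8 km side, hundreds of
    # events) 500 m buffers would cover the whole extent, so the pipeline
    # default scales the buffer to a few cell widths.
    buffer_m: float = 100.0
    vulnerability_cell_m: float = 500.0
    connectivity: int = 8
    seed: int = 0


@dataclass
class PipelineResult:
    region: SyntheticRegion
    hazard_map: Raster
    hazard_report: object
    holdout_auc: float
    hazard_frequency: FrequencyTable
    vulnerability: Raster
    damage_total: Raster
    risk: RiskLayers
    report: dict


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Synthetic region -> hazard -> vulnerability -> damage -> risk.

    Deterministic under a fixed config (every stochastic step derives from
    ``config.seed``).  When ``out_dir`` is given, all rasters, vectors, tables
    and the report JSON are written there.
    """
    t0 = time.time()
    region_cfg = dataclasses.replace(config.region, seed=config.seed)
    region = generate_region(region_cfg, config.planted)
    logger.info("region generated in %.1fs", time.time() - t0)

    # --- hazard
    inventory = DisasterInventory(region.events_xy, provenance="synthetic planted events")
    train_idx, hold_idx = split_inventory(len(inventory), config.train_fraction, config.seed)
    train_inv, hold_inv = inventory.subset(train_idx), inventory.subset(hold_idx)
    negatives = sample_negatives(
        inventory,
        region.stack.grid,
        region.river_mask,
        n=len(train_inv),
        buffer_m=config.buffer_m,
        seed=config.seed,
        nodata_mask=region.stack.nodata_mask(),
    )
    pos = extract_features(train_inv, region.stack, label=1)
    neg = extract_features(negatives, region.stack, label=0)
    samples = SampleSet.concatenate(pos, neg)

    if config.model == "iv":
        hz_map, _iv_tables = information_value_map(train_inv, region.stack)
        hz_report = None
    else:
        model, hz_report = tune_and_fit(samples, HazardModelConfig(seed=config.seed))
        hz_map = predict_hazard(model, region.stack)

    hold_neg = sample_negatives(
        inventory,
        region.stack.grid,
        region.river_mask,
        n=max(len(hold_inv), 1),
        buffer_m=config.buffer_m,
        seed=config.seed + 1,
        nodata_mask=region.stack.nodata_mask(),
    )
    auc, _curve, _dropped = roc_auc(hz_map, hold_inv.coords, hold_neg.coords)

    hz_breaks = jenks_breaks_raster(hz_map.raster, k=5, seed=config.seed)
    hz_classified = classify(hz_map.raster, hz_breaks)
    hz_freq = frequency_table(hz_classified, hold_inv.coords)
    logger.info("hazard stage done in %.1fs (AUC %.3f)", time.time() - t0, auc)

    # --- vulnerability
    vi, vi_classified, vi_metrics = vulnerability_map(
        region.stack.landuse,
        cell_size=config.vulnerability_cell_m,
        connectivity=config.connectivity,
        jenks_seed=config.seed,
    )

    # --- damage
    runoff = runoff_from_landcover(region.stack.precipitation, region.stack.landuse)
    qwr = water_conservation(region.stack.precipitation, runoff, region.evapotranspiration)
    ls = ls_factor(region.stack.elevation)
    c = c_factor(region.stack.ndvi)
    p = p_factor(region.stack.landuse)
    _sep, _ser, sor = rusle(region.rainfall_erosivity, region.soil_erodibility, ls, c, p)
    dmg = potential_damage(qwr, sor, region.npp, region.population, jenks_seed=config.seed)
    logger.info("vulnerability + damage done in %.1fs", time.time() - t0)

    # --- risk
    hazard_component = (
        hz_map.raster
        if hz_map.is_probability
        else _score_to_unit(hz_map.raster)
    )
    risk = compose_risk(hazard_component, vi, dmg.total_damage, jenks_seed=config.seed)
    config_echo = {
        "seed": config.seed,
        "model": config.model,
        "train_fraction": config.train_fraction,
        "buffer_m": config.buffer_m,
        "vulnerability_cell_m": config.vulnerability_cell_m,
        "connectivity": config.connectivity,
        "grid": dataclasses.asdict(region_cfg.grid),
        "planted_weights": dict(config.planted.factor_weights),
        "n_events": config.planted.n_events,
    }
    report = risk_report(risk, inventory, config_echo=config_echo)
    report["holdout_auc"] = auc
    report["hazard_frequency_table"] = hz_freq.to_frame().to_dict(orient="records")
    if hz_report is not None:
        report["hazard_model"] = {
            "chosen_n_trees": hz_report.chosen_n_trees,
            "chosen_m_features": hz_report.chosen_m_features,
            "cv_scores": list(hz_report.cv_scores),
            "importances": hz_report.importances,
        }
    logger.info("pipeline complete in %.1fs", time.time() - t0)

    result = PipelineResult(
        region=region,
        hazard_map=hz_map.raster,
        hazard_report=hz_report,
        holdout_auc=auc,
        hazard_frequency=hz_freq,
        vulnerability=vi,
        damage_total=dmg.total_damage,
        risk=risk,
        report=report,
    )
    if out_dir is not None:
        _write_artifacts(result, hz_classified, vi_classified, vi_metrics, dmg, Path(out_dir))
    return result


def _score_to_unit(score: Raster) -> Raster:
    """Map an unbounded score raster onto [0, 1] for the risk product."""
    from .geodata import range_standardize

    return range_standardize(score)


def _write_artifacts(result, hz_classified, vi_classified, vi_metrics, dmg, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, raster in [
        ("hazard", result.hazard_map),
        ("hazard_classified", hz_classified.raster),
        ("vulnerability", result.vulnerability),
        ("damage_total", result.damage_total),
        ("eco_loss", dmg.eco_loss),
        ("risk", result.risk.risk),
    ]:
        paths[name] = str(io.write_raster(raster, out / f"{name}.tif"))
    if vi_classified is not None:
        paths["vulnerability_classified"] = str(
            io.write_raster(vi_classified.raster, out / "vulnerability_classified.tif")
        )
    if result.risk.classified_risk is not None:
        paths["risk_classified"] = str(
            io.write_raster(result.risk.classified_risk.raster, out / "risk_classified.tif")
        )
    io.write_points(result.region.events_xy, out / "inventory.geojson")
    io.write_polylines(result.region.rivers, out / "rivers.geojson")
    io.write_polylines(result.region.faults, out / "faults.geojson")
    vi_metrics.to_csv(out / "vulnerability_metrics.csv", index=False)
    result.hazard_frequency.to_frame().to_csv(out / "hazard_frequency.csv", index=False)
    result.report["rasters"] = paths
    (out / "report.json").write_text(json.dumps(result.report, indent=2, default=float))
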