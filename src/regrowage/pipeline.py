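"""Configured, cached pipeline: simulate -> age -> grid -> stats -> carbon -> model.

Each stage writes its artifacts plus a sidecar manifest recording a key
derived from the stage's config section and the checksums of its inputs.
On re-run a stage whose key matches and whose outputs all exist is skipped
("cached"); changing one config section therefore re-runs only the stages
depending on it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import age_mapping, age_predictors, national_stats, spatial_summaries
from . import stack_io, synthetic_landscape
from .age_mapping import AgeParams
from .age_predictors import RFConfig
from .spatial_summaries import HotspotParams
from .synthetic_landscape import SimConfig

logger = logging.getLogger("regrowage")

STAGES = ("simulate", "age", "grid", "stats", "carbon", "model")


@dataclass
class PipelineConfig:
    outdir: Path = Path("regrow_out")
    seed: int = 0
    stages: tuple = STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    age: AgeParams = field(default_factory=AgeParams)
    hotspot: HotspotParams = field(default_factory=HotspotParams)
    cell_size: float = 480.0  # metres; a multiple of the synthetic 30 m pixel
    bins: tuple = national_stats.DEFAULT_BINS
    carbon_horizon: int = 25
    young_age_max: int = 5
    rf: RFConfig = field(default_factory=RFConfig)
    n_per_age: int = 200
    n_regions: int = 3

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        kw: dict = {}
        for key, val in d.items():
            if key == "sim":
                if "predictors" in val:
                    val = dict(val)
                    val["predictors"] = tuple(
                        synthetic_landscape.PredictorSpec(**p) for p in val["predictors"])
                if "shape" in val:
                    val["shape"] = tuple(val["shape"])
                if "year_range" in val:
                    val["year_range"] = tuple(val["year_range"])
                kw["sim"] = dataclasses.replace(cfg.sim, **val)
            elif key == "age":
                kw["age"] = dataclasses.replace(cfg.age, **val)
            elif key == "hotspot":
                if "percentiles" in val:
                    val = dict(val)
                    val["percentiles"] = tuple(val["percentiles"])
                kw["hotspot"] = dataclasses.replace(cfg.hotspot, **val)
            elif key == "rf":
                for g in ("ntree_grid", "mtry_grid"):
                    if g in val:
                        val = dict(val)
                        val[g] = tuple(val[g])
                kw["rf"] = dataclasses.replace(cfg.rf, **val)
            elif key == "bins":
                kw["bins"] = tuple(tuple(b) for b in val)
            elif key == "stages":
                kw["stages"] = tuple(val)
            elif key == "outdir":
                kw["outdir"] = Path(val)
            else:
                kw[key] = val
        out = dataclasses.replace(cfg, **kw)
        # the global seed propagates to every stochastic stage unless overridden
        if "sim" not in d or "seed" not in d.get("sim", {}):
            out = dataclasses.replace(out, sim=dataclasses.replace(out.sim, seed=out.seed))
        if "rf" not in d or "seed" not in d.get("rf", {}):
            out = dataclasses.replace(out, rf=dataclasses.replace(out.rf, seed=out.seed))
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# Caching helpers
# ---------------------------------------------------------------------------

def _digest_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _stage_key(section, inputs: list[Path]) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, frozenset)):
            return sorted(map(str, o)) if isinstance(o, frozenset) else str(o)
        if isinstance(o, np.integer):
            return int(o)
        raise TypeError(type(o))

    payload = {
        "config": json.loads(json.dumps(section, default=default)),
        "inputs": {str(p): _digest_file(p) for p in sorted(map(Path, inputs))},
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _cached(manifest_path: Path, key: str, outputs: list[Path]) -> bool:
    if not manifest_path.exists():
        return False
    try:
        rec = json.loads(manifest_path.read_text())
    except ValueError:
        return False
    return rec.get("key") == key and all(Path(p).exists() for p in rec.get("outputs", []))


def _record(manifest_path: Path, key: str, seed, outputs: list[Path]) -> None:
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    manifest_path.write_text(json.dumps(
        {"key": key, "seed": seed, "outputs": [str(p) for p in outputs]}, indent=1))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    mdir = out / "manifests"
    manifest: dict[str, dict] = {}

    paths = {
        "stack_dir": out / "stack",
        "mask": out / "plantation_mask.tif",
        "pred_dir": out / "predictors",
        "carbon_rate": out / "carbon_rate.tif",
        "countries_geojson": out / "countries.geojson",
        "countries_tif": out / "countries.tif",
        "effects": out / "true_effects.json",
        "age": out / f"age_{config.age.target_year}.tif",
        "grid_csv": out / "grid_summary.csv",
        "grid_geojson": out / "grid_summary.geojson",
        "country_age": out / "country_age.csv",
        "country_summary": out / "country_summary.csv",
        "share_ratio": out / "share_ratio.csv",
        "regional": out / "regional_summary.csv",
        "distribution": out / "age_distribution.csv",
        "carbon": out / "carbon.csv",
        "importance": out / "importance.csv",
        "pd_curves": out / "partial_dependence.csv",
        "rf_report": out / "rf_report.json",
    }

    def stage_enabled(name):
        return name in config.stages

    def run_stage(name, section, inputs, outputs, builder):
        if not stage_enabled(name):
            manifest[name] = {"status": "skipped", "outputs": []}
            return
        key = _stage_key(section, [p for p in inputs if Path(p).exists()])
        mpath = mdir / f"{name}.json"
        if _cached(mpath, key, outputs):
            manifest[name] = {"status": "cached", "outputs": [str(p) for p in outputs]}
            logger.info("stage %s: cached", name)
            return
        logger.info("stage %s: running", name)
        try:
            builder()
        except Exception as exc:
            raise RuntimeError(
                f"stage {name!r} failed (inputs: {[str(p) for p in inputs]}): {exc}"
            ) from exc
        _record(mpath, key, config.seed, outputs)
        manifest[name] = {"status": "built", "outputs": [str(p) for p in outputs]}

    # -- simulate -----------------------------------------------------------
    def build_simulate():
        predictors, effects = synthetic_landscape.simulate_predictors(config.sim)
        stack, mask = synthetic_landscape.simulate_stack(config.sim, predictors, effects)
        stack_io.write_class_stack(stack, paths["stack_dir"])
        stack_io.write_mask(mask, paths["mask"])
        paths["pred_dir"].mkdir(parents=True, exist_ok=True)
        for name, arr in predictors.items():
            stack_io.write_raster(paths["pred_dir"] / f"{name}.tif",
                                  arr.astype(np.float32), config.sim.georef)
        stack_io.write_raster(paths["carbon_rate"],
                              synthetic_landscape.simulate_carbon_rates(config.sim)
                              .astype(np.float32), config.sim.georef)
        features, craster, names = synthetic_landscape.make_countries(config.sim)
        stack_io.write_geojson(features, paths["countries_geojson"])
        stack_io.write_raster(paths["countries_tif"], craster, config.sim.georef)
        paths["effects"].write_text(json.dumps(effects, indent=1))

    sim_outputs = [paths["mask"], paths["carbon_rate"], paths["countries_geojson"],
                   paths["countries_tif"], paths["effects"]]
    run_stage("simulate", {"sim": config.sim}, [], sim_outputs, build_simulate)

    stack_files = sorted(paths["stack_dir"].glob("classes_*.tif"))

    # -- age ----------------------------------------------------------------
    def build_age():
        stack = stack_io.read_class_stack(stack_files, config.sim.year_range,
                                          pixel_area=config.sim.pixel_area)
        age = age_mapping.compute_age(stack, config.age)
        mask = stack_io.read_mask(paths["mask"])
        age = age_mapping.apply_mask(age, mask)
        n_regen = int((age.ages > 0).sum())
        logger.info("age stage: %d regenerating pixels", n_regen)
        stack_io.write_age_map(age, paths["age"])

    age_inputs = stack_files + [paths["mask"]] if stack_files else []
    run_stage("age", {"age": config.age}, age_inputs, [paths["age"]], build_age)

    def load_age():
        return stack_io.read_age_map(paths["age"], config.age.target_year,
                                     pixel_area=config.sim.pixel_area)

    # -- grid ---------------------------------------------------------------
    def build_grid():
        age = load_age()
        grid = spatial_summaries.aggregate_grid(age, config.cell_size, config.hotspot)
        grid.to_csv(paths["grid_csv"], index=False)
        stack_io.write_geojson(
            spatial_summaries.grid_to_geojson(grid, config.cell_size, age.georef),
            paths["grid_geojson"])

    run_stage("grid", {"hotspot": config.hotspot, "cell_size": config.cell_size},
              [paths["age"]],
              [paths["grid_csv"], paths["grid_geojson"]], build_grid)

    # -- stats --------------------------------------------------------------
    region_lookup = synthetic_landscape.assign_regions(config.sim, config.n_regions)

    def build_stats():
        age = load_age()
        craster, _, _ = stack_io.read_raster(paths["countries_tif"])
        table = national_stats.tabulate_by_country(age, craster, region_lookup)
        table.to_csv(paths["country_age"], index=False)
        summary = national_stats.country_summary(table)
        summary.to_csv(paths["country_summary"], index=False)
        if summary["old_area"].sum() > 0:
            national_stats.share_ratio(summary).to_csv(paths["share_ratio"], index=False)
        else:
            pd.DataFrame(columns=["country", "old_share", "all_share", "ratio"]
                         ).to_csv(paths["share_ratio"], index=False)
        national_stats.regional_summary(table).to_csv(paths["regional"], index=False)
        stack = stack_io.read_class_stack(stack_files, config.sim.year_range,
                                          pixel_area=config.sim.pixel_area)
        region_raster = _region_raster(craster, region_lookup)
        rnames = {i: lab for i, lab in enumerate(sorted(set(region_lookup.values())))}
        dist = national_stats.age_distribution(
            table, stack, region_raster, rnames, config.bins, config.age.target_year)
        dist.to_csv(paths["distribution"], index=False)

    stats_inputs = [paths["age"], paths["countries_tif"]] + stack_files
    run_stage("stats", {"bins": config.bins, "n_regions": config.n_regions},
              stats_inputs,
              [paths["country_age"], paths["country_summary"], paths["share_ratio"],
               paths["regional"], paths["distribution"]], build_stats)

    # -- carbon -------------------------------------------------------------
    def build_carbon():
        age = load_age()
        rates, _, _ = stack_io.read_raster(paths["carbon_rate"])
        craster, _, _ = stack_io.read_raster(paths["countries_tif"])
        est = national_stats.project_carbon(
            age, rates, config.carbon_horizon, config.young_age_max,
            country_raster=craster)
        rows = [{"country": "TOTAL", "area_ha": est.area_ha, "carbon_gtc": est.total_gtc}]
        if est.by_country is not None:
            rows += est.by_country.to_dict("records")
        pd.DataFrame(rows).to_csv(paths["carbon"], index=False)

    run_stage("carbon",
              {"horizon": config.carbon_horizon, "young_age_max": config.young_age_max},
              [paths["age"], paths["carbon_rate"], paths["countries_tif"]],
              [paths["carbon"]], build_carbon)

    # -- model --------------------------------------------------------------
    def build_model():
        age = load_age()
        sample = age_predictors.stratified_sample(
            age, config.n_per_age, seed=config.seed,
            age_range=(config.age.min_regrowth_years, config.age.max_age))
        rasters = {p.stem: stack_io.read_raster(p)[0]
                   for p in sorted(paths["pred_dir"].glob("*.tif"))}
        table = age_predictors.extract_predictors(sample, rasters)
        craster, _, _ = stack_io.read_raster(paths["countries_tif"])
        table["region"] = [region_lookup.get(int(c), "all")
                           for c in craster[table["row"], table["col"]]]
        reports = age_predictors.run_rf_protocol(
            table, list(rasters), config.rf, region_column="region")
        imp = pd.concat([r.importance.assign(region=region)
                         for region, r in reports.items()], ignore_index=True)
        imp.to_csv(paths["importance"], index=False)
        curves = pd.concat(
            [c.assign(region=region) for region, r in reports.items()
             for c in r.partial_dependence.values()], ignore_index=True)
        curves.to_csv(paths["pd_curves"], index=False)
        paths["rf_report"].write_text(json.dumps(
            {region: {"ntree": r.ntree, "mtry": r.mtry, "r2": r.r2, "rmse": r.rmse,
                      "n_train": r.n_train, "n_test": r.n_test}
             for region, r in reports.items()}, indent=1))

    pred_files = sorted(paths["pred_dir"].glob("*.tif")) if paths["pred_dir"].exists() else []
    run_stage("model", {"rf": config.rf, "n_per_age": config.n_per_age},
              [paths["age"], paths["countries_tif"]] + pred_files,
              [paths["importance"], paths["pd_curves"], paths["rf_report"]],
              build_model)

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _region_raster(country_raster: np.ndarray, region_lookup: dict) -> np.ndarray:
    labels = sorted(set(region_lookup.values()))
    lab_id = {lab: i for i, lab in enumerate(labels)}
    out = np.zeros(country_raster.shape, dtype=np.int64)
    for cid, lab in region_lookup.items():
        out[country_raster == cid] = lab_id[lab]
    return out
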