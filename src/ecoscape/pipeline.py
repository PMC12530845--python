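"""Config-driven orchestration of the full workflow.

``run_historical`` reproduces the retrospective analysis between two dated
maps: transition accounting, trajectory coding and the habitat model for
both epochs. ``run_scenario`` chains Markov demand estimation, scenario
adjustment, expansion-model fitting, CA allocation and the habitat model on
the simulated horizon map. Each run writes a directory with ``tables/``,
``rasters/``, ``log.txt`` and a machine-readable ``summary.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import allocation as _alloc
from . import habitat as _hab
from . import metrics as _met
from . import transitions as _tr
from .grid import (
    LULCMap,
    read_float_raster,
    read_lulc_raster,
    write_float_raster,
    write_lulc_raster,
)
from .models import HabitatQualityModel, LandUseChangeModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; loadable from YAML."""

    t1_path: str
    t2_path: str
    output_dir: str
    driver_dir: str | None = None
    mask_path: str | None = None
    scenario: str = "ND"
    horizon_steps: int = 1
    period_years: int = 14
    rng_seed: int = 0
    habitat: dict = field(default_factory=dict)  # k, thresholds, aggregation
    allocation: dict = field(default_factory=dict)  # AllocationConfig fields

    def __post_init__(self) -> None:
        if self.scenario not in ("ND", "EP", "custom"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _habitat_config(cfg: RunConfig) -> _hab.HabitatConfig:
    kw = dict(cfg.habitat)
    if "thresholds" in kw:
        kw["thresholds"] = tuple(kw["thresholds"])
    return _hab.HabitatConfig(**kw)


def _load_inputs(cfg: RunConfig):
    t1 = read_lulc_raster(cfg.t1_path)
    t1.epoch_label = "t1"
    t2 = read_lulc_raster(cfg.t2_path)
    t2.epoch_label = "t2"
    t1.grid.require_match(t2.grid, "input epochs")
    drivers = None
    if cfg.driver_dir is not None:
        layers, categorical = {}, set()
        for p in sorted(Path(cfg.driver_dir).glob("*.tif")):
            name = p.stem
            arr, grid = read_float_raster(p)
            t1.grid.require_match(grid, f"driver {name}")
            if name.startswith("cat_"):
                name = name[4:]
                categorical.add(name)
                arr = np.nan_to_num(arr).astype(np.int64)
            layers[name] = arr
        if layers:
            drivers = _alloc.DriverStack(t1.grid, layers, frozenset(categorical))
    mask = None
    if cfg.mask_path is not None:
        m, grid = read_float_raster(cfg.mask_path)
        t1.grid.require_match(grid, "restricted mask")
        mask = np.nan_to_num(m) > 0.5
    return t1, t2, drivers, mask


def _setup_output(cfg: RunConfig):
    out = Path(cfg.output_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logging.getLogger("ecoscape").addHandler(handler)
    logging.getLogger("ecoscape").setLevel(logging.INFO)
    return out, handler


def _habitat_outputs(lulc: LULCMap, cfg: RunConfig, out: Path, tag: str) -> dict:
    res = HabitatQualityModel(lulc, config=_habitat_config(cfg)).fit()
    write_float_raster(res.quality, lulc.grid, out / "rasters" / f"quality_{tag}.tif")
    write_float_raster(
        res.degradation, lulc.grid, out / "rasters" / f"degradation_{tag}.tif"
    )
    write_float_raster(
        res.grades.astype(np.float32), lulc.grid, out / "rasters" / f"grades_{tag}.tif"
    )
    res.grade_table.to_csv(out / "tables" / f"grade_summary_{tag}.csv")
    logger.info("habitat %s: mean Q %.4f, mean D %.4f", tag,
                res.mean_quality, res.mean_degradation)
    return {
        "mean_quality": res.mean_quality,
        "mean_degradation": res.mean_degradation,
        "grade_areas_km2": dict(
            zip(res.grade_table["label"], res.grade_table["area"])
        ),
    }


def run_historical(cfg: RunConfig) -> dict:
    """Retrospective analysis; returns the summary dict (also on disk)."""
    out, handler = _setup_output(cfg)
    try:
        t1, t2, _, _ = _load_inputs(cfg)
        logger.info("historical run: %d valid cells", t1.n_valid)
        tm = _tr.compute_transition_matrix(t1, t2)
        tm.to_csv(out / "tables" / "transition_matrix.csv")
        table = _tr.change_summary(tm)
        table.to_csv(out / "tables" / "change_summary.csv")
        _tr.transition_shares(tm).to_csv(
            out / "tables" / "transition_shares.csv", index=False
        )
        traj = _tr.trajectory_map(t1, t2)
        write_lulc_raster(
            LULCMap(t1.grid, traj.codes,
                    {int(c): str(c) for c in np.unique(traj.codes) if c != t1.grid.nodata_code},
                    "trajectory"),
            out / "rasters" / "trajectory.tif",
        )
        summary = {
            "stage": "historical",
            "valid_cells": t1.n_valid,
            "per_class": {
                str(c): {
                    "area_t1": float(table.loc[c, "area_t1"]),
                    "area_t2": float(table.loc[c, "area_t2"]),
                    "delta_area": float(table.loc[c, "delta_area"]),
                    "delta_rate": None
                    if np.isnan(table.loc[c, "delta_rate"])
                    else float(table.loc[c, "delta_rate"]),
                }
                for c in table.index
            },
            "habitat_t1": _habitat_outputs(t1, cfg, out, "t1"),
            "habitat_t2": _habitat_outputs(t2, cfg, out, "t2"),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    finally:
        logging.getLogger("ecoscape").removeHandler(handler)


def run_scenario(cfg: RunConfig) -> dict:
    """Scenario projection; returns the summary dict (also on disk)."""
    out, handler = _setup_output(cfg)
    try:
        t1, t2, drivers, mask = _load_inputs(cfg)
        if drivers is None:
            raise ValueError("scenario run requires a driver directory")
        model = LandUseChangeModel(
            t1, t2, drivers, period_years=cfg.period_years, seed=cfg.rng_seed
        )
        fitted = model.fit()
        if fitted.importances is not None:
            fitted.importances.to_csv(out / "tables" / "driver_importances.csv")
        alloc_cfg = _alloc.AllocationConfig(
            rng_seed=cfg.rng_seed, **cfg.allocation
        )
        sim = fitted.simulate(
            cfg.scenario, steps=cfg.horizon_steps, config=alloc_cfg,
            restricted_mask=mask,
        )
        sim.demand.to_csv(out / "tables" / f"demand_{cfg.scenario}.csv")
        write_lulc_raster(
            sim.lulc, out / "rasters" / f"lulc_{cfg.scenario}_horizon.tif"
        )
        base = _habitat_outputs(t2, cfg, out, "base")
        horizon = _habitat_outputs(sim.lulc, cfg, out, f"{cfg.scenario}_horizon")
        summary = {
            "stage": "scenario",
            "scenario": cfg.scenario,
            "demand_km2": {str(c): float(v) for c, v in sim.demand.items()},
            "achieved_km2": {
                str(c): float(v) for c, v in sim.lulc.class_areas_km2().items()
            },
            "residual_km2": {
                str(c): float(v) for c, v in sim.allocation.residuals.items()
            },
            "converged": sim.allocation.converged,
            "habitat_base": base,
            "habitat_horizon": horizon,
            "delta_mean_quality": horizon["mean_quality"] - base["mean_quality"],
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    finally:
        logging.getLogger("ecoscape").removeHandler(handler)


def run_validation(ref_t1: LULCMap, ref_t2: LULCMap, simulated: LULCMap) -> dict:
    """OA / Kappa / FOM between a simulated map and the reference pair."""
    cm = _met.confusion_matrix(ref_t2, simulated)
    oa, kappa = _met.oa_kappa(cm)
    fom = _met.figure_of_merit(ref_t1, ref_t2, simulated)
    return {"overall_accuracy": oa, "kappa": kappa, "figure_of_merit": fom}
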