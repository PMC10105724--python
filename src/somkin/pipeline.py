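"""End-to-end orchestration: simulate/ingest -> fit -> summarize -> train ->
map -> uncertainty -> latitudinal profiles, driven by one TOML config.

Every run writes a manifest (outputs, metrics, seeds, schema version) and is
reproducible bit-for-bit given the same config and seed for the deterministic
stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset, mapping, ml, synthetic
from .kinetics import PoolKinetics, fit_first_order

__all__ = ["RunConfig", "run_pipeline", "load_config"]

SCHEMA_VERSION = 1
_STAGES = ("simulate", "fit", "summarize", "train", "map", "profile")

log = logging.getLogger("somkin")


@dataclass
class RunConfig:
    """Validated pipeline configuration (see README for the TOML layout)."""

    out_dir: str = "somkin_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(_STAGES))
    # synthetic world
    n_sites: int = 400
    pool_model: str = "M3"
    raster_shape: tuple = (30, 60)
    # fit stage
    n_series: int = 10
    # train stage
    targets: list = field(default_factory=lambda: ["M3_k3"])
    methods: list = field(default_factory=lambda: ["rf"])
    repeats: int = 1
    rfe: bool = False
    cv_folds: int = 5
    cv_repeats: int = 1
    n_trees: int = 100
    # map stage
    uncertainty: str = "both"   # ph | trees | both | none
    band: float = 5.0
    # optional external inputs
    table_path: str | None = None

    def __post_init__(self):
        bad = [s for s in self.stages if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        if "map" in self.stages and "train" not in self.stages:
            raise ValueError("stage 'map' requires stage 'train' (no model)")
        if "profile" in self.stages and "map" not in self.stages:
            raise ValueError("stage 'profile' requires stage 'map'")
        if self.uncertainty not in ("ph", "trees", "both", "none"):
            raise ValueError("uncertainty must be ph|trees|both|none")
        if self.table_path is not None and not Path(self.table_path).exists():
            raise ValueError(f"table_path does not exist: {self.table_path}")


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from TOML; unknown keys are hard errors."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "raster_shape" in raw:
        raw["raster_shape"] = tuple(raw["raster_shape"])
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                "stages": list(config.stages), "outputs": {}, "metrics": {},
                "timestamps": {"start": time.time()}}
    scfg = synthetic.SyntheticConfig(n_sites=config.n_sites,
                                     pool_model=config.pool_model,
                                     seed=config.seed)
    state: dict = {}

    for stage in config.stages:
        t0 = time.time()
        log.info("stage %s: start", stage)
        try:
            _RUNNERS[stage](config, scfg, state, out, manifest)
        except Exception:
            manifest["failed_stage"] = stage
            with open(out / "manifest.partial.json", "w") as fh:
                json.dump(_jsonable(manifest), fh, indent=1)
            log.error("stage %s failed; partial manifest written", stage)
            raise
        log.info("stage %s: done in %.2fs", stage, time.time() - t0)

    manifest["timestamps"]["end"] = time.time()
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1)
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_simulate(config, scfg, state, out, manifest):
    if config.table_path:
        table, rejects = dataset.read_table(config.table_path)
        state["rasters"] = synthetic.gen_rasters(scfg, shape=config.raster_shape)
        manifest["metrics"]["n_records"] = len(table)
        manifest["metrics"]["n_rejected"] = len(rejects)
    else:
        rasters, sites = synthetic.gen_world(scfg, shape=config.raster_shape,
                                             seed=config.seed)
        state["rasters"] = rasters
        state["sites"] = sites
        table = synthetic.gen_kinetics_table(scfg, seed=config.seed)
        rejects = pd.DataFrame()
    state["table"] = table
    dataset.write_table(table, out / "kinetics_table.csv")
    rejects.to_csv(out / "rejects.csv", index=False)
    rdir = out / "rasters"
    rdir.mkdir(exist_ok=True)
    for name, r in state["rasters"].items():
        r.to_text(rdir / f"{name}.txt")
    manifest["outputs"]["table"] = str(out / "kinetics_table.csv")
    manifest["outputs"]["rasters"] = str(rdir)


def _stage_fit(config, scfg, state, out, manifest):
    """Fit multi-pool models to simulated incubation curves (sanity stage)."""
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_series) % (2 ** 31)
    npools = int(config.pool_model[1])
    table = state["table"]
    sub = table[table["model_type"] == config.pool_model].head(config.n_series)
    rows = []
    for (_, rec), s in zip(sub.iterrows(), rng_seeds):
        ks = [rec[f"k{j}"] for j in range(1, npools + 1)]
        fs = [rec[f"f{j}"] for j in range(1, npools + 1)]
        true = PoolKinetics(f=np.array(fs), k=np.array(ks), s0=1.0)
        series = synthetic.gen_incubation_series(
            true, noise_fraction=scfg.series_noise_fraction, seed=int(s))
        res = fit_first_order(series, n_pools=npools, s0=1.0)
        rows.append({"record_id": rec["record_id"], "r2": res.r2,
                     "rmse": res.rmse, "converged": res.converged,
                     **{f"k{j+1}_hat": res.params.k[j] for j in range(npools)},
                     **{f"f{j+1}_hat": res.params.f[j] for j in range(npools)}})
    fits = pd.DataFrame(rows)
    fits.to_csv(out / "series_fits.csv", index=False)
    manifest["outputs"]["series_fits"] = str(out / "series_fits.csv")
    manifest["metrics"]["fit_median_r2"] = float(fits["r2"].median())


def _stage_summarize(config, scfg, state, out, manifest):
    cmp = dataset.pool_comparison(state["table"])
    cmp["summary"].to_csv(out / "parameter_summary.csv", index=False)
    cmp["reference_checks"].to_csv(out / "reference_checks.csv", index=False)
    with open(out / "kw_tests.json", "w") as fh:
        json.dump(_jsonable(cmp["kw"]), fh, indent=1)
    manifest["outputs"]["summary"] = str(out / "parameter_summary.csv")
    for par, res in cmp["kw"].items():
        if isinstance(res, dict):
            manifest["metrics"][f"kw_p_{par}"] = res["p_value"]


def _stage_train(config, scfg, state, out, manifest):
    table = state.get("sites", state["table"])
    models = {}
    records = []
    for target in config.targets:
        model_tag, pool = target.split("_")
        if "sites" in state:
            pcfg = replace(scfg, pool_model=model_tag)
            y = synthetic.true_parameter_map(
                table[ml.COVARIATES], pcfg, seed=config.seed)[pool].to_numpy()
        else:
            sub = state["table"]
            sub = sub[sub["model_type"] == model_tag]
            y = sub[pool].to_numpy()
            table = sub
        X = table[ml.COVARIATES]
        best_per_method = []
        for method in config.methods:
            if config.repeats > 1:
                m, hist = ml.repeat_and_select(
                    X, y, method=method, n_repeats=config.repeats,
                    seed=config.seed, target_name=target, rfe=config.rfe,
                    cv_folds=config.cv_folds, cv_repeats=config.cv_repeats,
                    n_trees=config.n_trees)
            else:
                m = ml.train_model(
                    X, y, method=method, target_name=target, rfe=config.rfe,
                    seed=config.seed, cv_folds=config.cv_folds,
                    cv_repeats=config.cv_repeats, n_trees=config.n_trees)
            best_per_method.append(m)
            records.append({"target": target, "method": method,
                            "cv_r2": m.cv_r2, "test_r2": m.test_metrics["r2"],
                            "test_ccc": m.test_metrics["ccc"],
                            "test_rmsen": m.test_metrics["rmsen"],
                            "aic": m.aic,
                            "features": ",".join(m.selected_features)})
        winner = ml.compare_by_aic(best_per_method)[0]
        models[target] = winner
        manifest["metrics"][f"{target}_best_method"] = winner.method
        manifest["metrics"][f"{target}_test_r2"] = winner.test_metrics["r2"]
    state["models"] = models
    pd.DataFrame(records).to_csv(out / "model_performance.csv", index=False)
    manifest["outputs"]["model_performance"] = str(out / "model_performance.csv")


def _stage_map(config, scfg, state, out, manifest):
    rasters = state["rasters"]
    grids = {}
    mdir = out / "maps"
    mdir.mkdir(exist_ok=True)
    for target, model in state["models"].items():
        grid = mapping.predict_grid(model, rasters)
        grid.mean.to_text(mdir / f"{target}_mean.txt")
        entry = {"mean": str(mdir / f"{target}_mean.txt")}
        if config.uncertainty in ("ph", "both") and "pH_p5" in rasters:
            g = mapping.input_uncertainty_ph(model, rasters,
                                             rasters["pH_p5"],
                                             rasters["pH_p95"])
            g.reun.to_text(mdir / f"{target}_reun_ph.txt")
            entry["reun_ph"] = str(mdir / f"{target}_reun_ph.txt")
            manifest["metrics"][f"{target}_reun_ph_mean"] = float(
                np.nanmean(g.reun.values))
        if config.uncertainty in ("trees", "both") and model.method == "rf":
            g = mapping.structure_uncertainty(model, rasters)
            g.reun.to_text(mdir / f"{target}_reun_trees.txt")
            entry["reun_trees"] = str(mdir / f"{target}_reun_trees.txt")
            manifest["metrics"][f"{target}_reun_trees_mean"] = float(
                np.nanmean(g.reun.values))
        grids[target] = grid
        manifest["outputs"][f"map_{target}"] = entry
    state["grids"] = grids


def _stage_profile(config, scfg, state, out, manifest):
    pdir = out / "profiles"
    pdir.mkdir(exist_ok=True)
    for target, grid in state["grids"].items():
        prof = mapping.latitudinal_profile(grid, band=config.band)
        prof.to_csv(pdir / f"{target}_profile.csv", index=False)
        manifest["outputs"][f"profile_{target}"] = str(
            pdir / f"{target}_profile.csv")


_RUNNERS = {"simulate": _stage_simulate, "fit": _stage_fit,
            "summarize": _stage_summarize, "train": _stage_train,
            "map": _stage_map, "profile": _stage_profile}
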