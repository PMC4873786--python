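"""End-to-end orchestration: simulate -> thin -> absences -> select-vars ->
evaluate -> ensemble -> importance -> risk.

Two entry points:

- :func:`run_analysis` executes the whole workflow in memory from an
  :class:`AnalysisConfig` and returns an :class:`AnalysisResult`; this is
  what tests and scripted experiments use.
- :func:`run_stage` / :func:`run_full` execute the same stages against a
  run directory, reading and writing the on-disk artifact formats (ASCII
  grids, CSVs, a JSON manifest), so any stage can be re-run from the
  previous stages' files alone.

All randomness flows from one master seed through
:func:`enmrisk.seeds.derive_seed`, so two runs from one config agree
byte-for-byte on every tabular output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DependencyError
from .evaluation import (
    SplitPlan,
    build_ensemble,
    ensemble_cv_records,
    ensemble_predict,
    importance_table,
    run_design,
    select_members,
    welch_t,
)
from .grids import GridSpec, RasterGrid, RegionMap, normalize01, read_raster, write_raster
from .occurrences import (
    AbsenceDataset,
    PresenceCellSet,
    generate_pseudo_absences,
    read_occurrences,
    thin_to_cells,
)
from .predictors import PredictorStack, extract_values, vif_stepwise
from .occurrences import assemble_response
from .risk import PressureInputs, build_pressure_layer, make_risk_map
from .sdm_models import METHODS, ModelSpec
from .seeds import derive_seed
from .synthetic import (
    VirtualSpeciesConfig,
    generate_environment,
    generate_pressure_inputs,
    generate_virtual_species,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "thin", "absences", "select-vars", "evaluate", "ensemble", "importance", "risk")

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "run_stage", "run_full", "STAGES"]


@dataclass
class AnalysisConfig:
    """Everything one run needs; defaults are the reference study conditions."""

    species: VirtualSpeciesConfig = field(default_factory=VirtualSpeciesConfig)
    methods: tuple = METHODS
    n_datasets: int = 10
    n_per_dataset: int = 1000
    r_inner_km: float = 50.0
    r_outer_km: float = 100.0
    train_fraction: float = 0.70
    n_repeats: int = 10
    vif_threshold: float = 10.0
    pinned_variables: list | None = None
    auc_floor: float = 0.8
    drop_methods: list = field(default_factory=list)
    n_shuffles: int = 3
    n_regions: int = 4
    normalize_pressure_first: bool = False
    master_seed: int = 0

    def with_seed(self, master_seed: int) -> "AnalysisConfig":
        cfg = replace(self, master_seed=master_seed)
        cfg.species = replace(self.species, seed=derive_seed(master_seed, "simulate"))
        return cfg


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    stack: PredictorStack
    truth: object
    presences: PresenceCellSet
    absences: list
    retained_vars: list
    vif_removals: list
    records: pd.DataFrame
    retained_methods: list
    selection_log: pd.DataFrame
    ensemble: object
    em_records: pd.DataFrame
    welch: tuple
    importance: pd.DataFrame
    suitability: RasterGrid
    pressure: RasterGrid
    risk: RasterGrid

    @property
    def ensemble_mean_auc(self) -> float:
        return float(self.em_records["auc"].mean())

    @property
    def best_member_mean_auc(self) -> float:
        return max(self.ensemble.member_mean_auc.values())

    def truth_correlation(self) -> float:
        m = self.suitability.mask & self.truth.true_suitability.mask
        return float(np.corrcoef(self.suitability.values[m], self.truth.true_suitability.values[m])[0, 1])


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Execute the full workflow in memory and return all artifacts."""
    t0 = time.time()
    species = replace(config.species, seed=derive_seed(config.master_seed, "simulate"))
    stack = generate_environment(species)
    truth, occ = generate_virtual_species(stack, species)
    presences = thin_to_cells(occ, species.grid)
    logger.info("simulate+thin: %d records -> %d presence cells", len(occ), len(presences))

    mask_grid = RasterGrid(species.grid, np.zeros(species.grid.shape), stack.combined_mask)
    absences = generate_pseudo_absences(
        presences,
        mask_grid,
        n_per_dataset=config.n_per_dataset,
        n_datasets=config.n_datasets,
        r_inner_km=config.r_inner_km,
        r_outer_km=config.r_outer_km,
        seed=derive_seed(config.master_seed, "absences"),
    )

    if config.pinned_variables:
        retained_vars, removals = list(config.pinned_variables), []
    else:
        table0 = extract_values(stack, assemble_response(presences, absences[0]))
        retained_vars, removals = vif_stepwise(
            table0[stack.names], threshold=config.vif_threshold
        )
    logger.info("select-vars: retained %d of %d (%s removed)", len(retained_vars), len(stack.names), [r[0] for r in removals])

    sub_stack = stack.subset(retained_vars)
    plan = SplitPlan(config.train_fraction, config.n_repeats, derive_seed(config.master_seed, "evaluate"))
    specs = [ModelSpec(m) for m in config.methods]
    records, final_models, tables, cv_preds = run_design(specs, absences, presences, sub_stack, plan)

    retained_methods, selection_log = select_members(records, config.auc_floor, config.drop_methods)
    ensemble = build_ensemble(records, final_models, retained_methods)
    em_records = ensemble_cv_records(ensemble, tables, cv_preds)
    indiv = records[records["method"].isin(retained_methods)]["auc"].to_numpy()
    welch = welch_t(em_records["auc"].to_numpy(), indiv)

    imp = importance_table(
        ensemble, tables, n_shuffles=config.n_shuffles, seed=derive_seed(config.master_seed, "importance")
    )

    emmw = ensemble_predict(ensemble, sub_stack)
    suitability = normalize01(emmw)
    pressure_inputs = generate_pressure_inputs(
        species.grid, n_regions=config.n_regions, seed=derive_seed(config.master_seed, "pressure")
    )
    pressure = build_pressure_layer(
        pressure_inputs, species.grid, normalize_first=config.normalize_pressure_first
    )
    risk = make_risk_map(suitability, pressure)
    logger.info("run_analysis finished in %.1f s", time.time() - t0)
    return AnalysisResult(
        config=config,
        stack=stack,
        truth=truth,
        presences=presences,
        absences=absences,
        retained_vars=retained_vars,
        vif_removals=removals,
        records=records,
        retained_methods=retained_methods,
        selection_log=selection_log,
        ensemble=ensemble,
        em_records=em_records,
        welch=welch,
        importance=imp,
        suitability=suitability,
        pressure=pressure,
        risk=risk,
    )


# ---------------------------------------------------------------------------
# File-based staged pipeline
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = {
    "simulate": {
        "n_rows", "n_cols", "lon_origin", "lat_origin", "cell_size", "n_vars",
        "autocorr_cells", "collinear_pairs", "effect_vars", "linear_coefs",
        "quadratic_coefs", "intercept", "n_presences", "n_regions",
    },
    "absences": {"n_per_dataset", "n_datasets", "r_inner_km", "r_outer_km"},
    "select_vars": {"vif_threshold", "pinned_variables"},
    "evaluate": {"methods", "train_fraction", "n_repeats"},
    "ensemble": {"auc_floor", "drop_methods"},
    "importance": {"n_shuffles"},
    "risk": {"normalize_pressure_first"},
}
_TOP_KEYS = {"master_seed"} | set(_CONFIG_SECTIONS)


def load_config(path) -> AnalysisConfig:
    """Load a sectioned YAML run config; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    for section, allowed in _CONFIG_SECTIONS.items():
        extra = set(raw.get(section) or {}) - allowed
        if extra:
            raise ConfigError(f"unknown key(s) in [{section}]: {sorted(extra)}")
    sim = raw.get("simulate") or {}
    grid_keys = {"n_rows", "n_cols", "lon_origin", "lat_origin", "cell_size"}
    species_kwargs = {k: v for k, v in sim.items() if k not in grid_keys | {"n_regions"}}
    if "collinear_pairs" in species_kwargs:
        species_kwargs["collinear_pairs"] = [tuple(p) for p in species_kwargs["collinear_pairs"]]
    default_grid = VirtualSpeciesConfig().grid
    grid = GridSpec(
        n_rows=sim.get("n_rows", default_grid.n_rows),
        n_cols=sim.get("n_cols", default_grid.n_cols),
        lon_origin=sim.get("lon_origin", default_grid.lon_origin),
        lat_origin=sim.get("lat_origin", default_grid.lat_origin),
        cell_size=sim.get("cell_size", default_grid.cell_size),
    )
    species = VirtualSpeciesConfig(grid=grid, **species_kwargs)
    flat: dict = {}
    for section in ("absences", "select_vars", "evaluate", "ensemble", "importance", "risk"):
        flat.update(raw.get(section) or {})
    if "methods" in flat:
        flat["methods"] = tuple(flat["methods"])
    return AnalysisConfig(
        species=species,
        master_seed=raw.get("master_seed", 0),
        n_regions=sim.get("n_regions", 4),
        **flat,
    )


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _manifest_path(out_dir: Path) -> Path:
    return out_dir / "manifest.json"


def _load_manifest(out_dir: Path) -> dict:
    p = _manifest_path(out_dir)
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _save_manifest(out_dir: Path, manifest: dict) -> None:
    _manifest_path(out_dir).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(out_dir: Path, relpath: str, stage: str) -> Path:
    p = out_dir / relpath
    if not p.exists():
        raise DependencyError(f"stage {stage!r} needs missing upstream artifact {relpath!r}; run its producing stage first")
    return p


def _read_stack(out_dir: Path, names: list[str]) -> PredictorStack:
    return PredictorStack({n: read_raster(out_dir / "layers" / f"{n}.asc") for n in names})


def run_stage(name: str, config: AnalysisConfig, out_dir) -> None:
    """Run one pipeline stage against a run directory."""
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}; stages are {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(out_dir)
    manifest["config_hash"] = _config_hash(config)
    manifest["master_seed"] = config.master_seed
    t0 = time.time()
    info: dict = {}

    species = replace(config.species, seed=derive_seed(config.master_seed, "simulate"))

    if name == "simulate":
        stack = generate_environment(species)
        truth, occ = generate_virtual_species(stack, species)
        (out_dir / "layers").mkdir(exist_ok=True)
        for n, g in stack.layers.items():
            write_raster(g, out_dir / "layers" / f"{n}.asc")
        write_raster(truth.true_suitability, out_dir / "true_suitability.asc")
        occ.to_csv(out_dir / "occurrences.csv", index=False)
        pin = generate_pressure_inputs(species.grid, config.n_regions, derive_seed(config.master_seed, "pressure"))
        (out_dir / "pressure").mkdir(exist_ok=True)
        write_raster(RasterGrid(pin.regions.spec, pin.regions.region_id.astype(float)), out_dir / "pressure" / "regions.asc")
        write_raster(pin.discharge, out_dir / "pressure" / "discharge.asc")
        pd.DataFrame(
            {"region_id": list(pin.national_total), "total": list(pin.national_total.values())}
        ).to_csv(out_dir / "pressure" / "totals.csv", index=False)
        info = {"n_layers": len(stack.names), "n_occurrences": len(occ), "seed": species.seed}

    elif name == "thin":
        occ = read_occurrences(_require(out_dir, "occurrences.csv", name))
        presences = thin_to_cells(occ, species.grid)
        presences.to_frame().to_csv(out_dir / "presence_cells.csv", index=False)
        info = {"n_records": len(occ), "n_presence_cells": len(presences)}

    elif name == "absences":
        presences = _read_presences(out_dir, species.grid, name)
        stack = _read_stack(out_dir, species.var_names)
        mask_grid = RasterGrid(species.grid, np.zeros(species.grid.shape), stack.combined_mask)
        seed = derive_seed(config.master_seed, "absences")
        datasets = generate_pseudo_absences(
            presences, mask_grid,
            n_per_dataset=config.n_per_dataset, n_datasets=config.n_datasets,
            r_inner_km=config.r_inner_km, r_outer_km=config.r_outer_km, seed=seed,
        )
        rows = [
            {"dataset_id": d.dataset_id, "lon": p[0], "lat": p[1]}
            for d in datasets
            for p in d.points
        ]
        pd.DataFrame(rows).to_csv(out_dir / "absences.csv", index=False)
        info = {"n_datasets": len(datasets), "n_points": sum(len(d) for d in datasets), "seed": seed}

    elif name == "select-vars":
        if config.pinned_variables:
            retained, removals = list(config.pinned_variables), []
        else:
            presences = _read_presences(out_dir, species.grid, name)
            datasets = _read_absences(out_dir, name)
            stack = _read_stack(out_dir, species.var_names)
            table0 = extract_values(stack, assemble_response(presences, datasets[0]))
            retained, removals = vif_stepwise(table0[stack.names], threshold=config.vif_threshold)
        (out_dir / "retained_variables.txt").write_text("\n".join(retained) + "\n")
        pd.DataFrame(removals, columns=["variable", "vif_at_removal"]).to_csv(
            out_dir / "vif_removals.csv", index=False
        )
        info = {"retained": retained, "removed": [r[0] for r in removals]}

    elif name == "evaluate":
        presences = _read_presences(out_dir, species.grid, name)
        datasets = _read_absences(out_dir, name)
        retained = _require(out_dir, "retained_variables.txt", name).read_text().split()
        stack = _read_stack(out_dir, species.var_names).subset(retained)
        plan = SplitPlan(config.train_fraction, config.n_repeats, derive_seed(config.master_seed, "evaluate"))
        specs = [ModelSpec(m) for m in config.methods]
        records, final_models, tables, cv_preds = run_design(specs, datasets, presences, stack, plan)
        records.to_csv(out_dir / "eval_records.csv", index=False)
        joblib.dump(
            {"final_models": final_models, "tables": tables, "cv_predictions": cv_preds},
            out_dir / "evaluate_state.joblib",
        )
        info = {"n_records": len(records), "n_model_fits": len(records), "plan_seed": plan.seed}

    elif name == "ensemble":
        records = pd.read_csv(_require(out_dir, "eval_records.csv", name))
        state = joblib.load(_require(out_dir, "evaluate_state.joblib", name))
        retained_methods, sel_log = select_members(records, config.auc_floor, config.drop_methods)
        ensemble = build_ensemble(records, state["final_models"], retained_methods)
        em_records = ensemble_cv_records(ensemble, state["tables"], state["cv_predictions"])
        sel_log.to_csv(out_dir / "member_selection.csv", index=False)
        pd.DataFrame(
            {"method": list(ensemble.weights), "weight": list(ensemble.weights.values()),
             "mean_auc": [ensemble.member_mean_auc[m] for m in ensemble.weights]}
        ).to_csv(out_dir / "ensemble_weights.csv", index=False)
        em_records.to_csv(out_dir / "emmw_records.csv", index=False)
        retained = _require(out_dir, "retained_variables.txt", name).read_text().split()
        stack = _read_stack(out_dir, species.var_names).subset(retained)
        emmw = ensemble_predict(ensemble, stack)
        write_raster(normalize01(emmw), out_dir / "suitability.asc")
        joblib.dump(ensemble, out_dir / "ensemble.joblib")
        indiv = records[records["method"].isin(retained_methods)]["auc"].to_numpy()
        t, df, p = welch_t(em_records["auc"].to_numpy(), indiv)
        (out_dir / "welch_test.json").write_text(json.dumps({"t": t, "df": df, "p": p}))
        info = {"retained_methods": retained_methods, "emmw_mean_auc": float(em_records["auc"].mean())}

    elif name == "importance":
        state = joblib.load(_require(out_dir, "evaluate_state.joblib", name))
        ensemble = joblib.load(_require(out_dir, "ensemble.joblib", name))
        imp = importance_table(
            ensemble, state["tables"], n_shuffles=config.n_shuffles,
            seed=derive_seed(config.master_seed, "importance"),
        )
        imp.rename_axis("method").to_csv(out_dir / "importance.csv")
        info = {"n_methods": len(imp) - 1}

    elif name == "risk":
        suit = read_raster(_require(out_dir, "suitability.asc", name))
        regions_grid = read_raster(_require(out_dir, "pressure/regions.asc", name))
        discharge = read_raster(_require(out_dir, "pressure/discharge.asc", name))
        totals_df = pd.read_csv(_require(out_dir, "pressure/totals.csv", name))
        pin = PressureInputs(
            regions=RegionMap(regions_grid.spec, regions_grid.values.astype(int)),
            national_total={int(r.region_id): float(r.total) for r in totals_df.itertuples()},
            discharge=discharge,
        )
        pressure = build_pressure_layer(pin, suit.spec, normalize_first=config.normalize_pressure_first)
        write_raster(pressure, out_dir / "pressure.asc")
        risk = make_risk_map(suit, pressure)
        write_raster(risk, out_dir / "risk.asc")
        info = {"risk_max": float(risk.values[risk.mask].max())}

    manifest["stages"][name] = {"wall_s": round(time.time() - t0, 3), **info}
    _save_manifest(out_dir, manifest)
    logger.info("stage %s done in %.1f s", name, time.time() - t0)


def _read_presences(out_dir: Path, grid: GridSpec, stage: str) -> PresenceCellSet:
    df = pd.read_csv(_require(out_dir, "presence_cells.csv", stage))
    cells = list(zip(df["row"].astype(int), df["col"].astype(int)))
    return PresenceCellSet(spec=grid, cells=cells, centroids=df[["lon", "lat"]].to_numpy())


def _read_absences(out_dir: Path, stage: str) -> list:
    df = pd.read_csv(_require(out_dir, "absences.csv", stage))
    out = []
    for ds_id, grp in df.groupby("dataset_id", sort=True):
        out.append(AbsenceDataset(dataset_id=int(ds_id), points=grp[["lon", "lat"]].to_numpy(), seed=-1))
    return out


def run_full(config: AnalysisConfig, out_dir) -> Path:
    """Run every stage in order; abort (retaining partial output) on failure."""
    out_dir = Path(out_dir)
    for stage in STAGES:
        try:
            run_stage(stage, config, out_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return out_dir
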