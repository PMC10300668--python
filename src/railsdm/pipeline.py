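"""Configuration, orchestration and logging for the full analysis.

``run_pipeline`` chains the stages in method order: simulate a landscape
with known truth → bias-correct the occurrence data (dedup, region mask,
pseudoabsences, density stratification, NMD thinning, parity balancing) →
assemble features, screen collinearity, select variables with RF → fit the
four-member ensemble → evaluate and map current suitability → refit a
climate-only model and project change under future scenarios.

All randomness derives from one top-level seed via fixed offsets
(generation seed, thinning seed + 1000, selection + 2000, members + 3000,
importance + 4000, GCM analogues + 5000 + i), so a run is bit-reproducible.
The manifest records the record-count funnel, chosen NMDs, tuning winners
and metric summaries; it contains no wall-clock state, so identical seeds
give bit-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import ensemble as ens_mod
from . import prep as prep_mod
from . import projection as proj_mod
from . import synthetic as syn_mod
from .rasters import (
    EnvStack,
    GridSpec,
    OccurrenceSet,
    SuitabilityMap,
    write_ascii_grid,
    write_occurrences,
    write_stack,
)

log = logging.getLogger("railsdm")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Model):
    # 250 km × 250 km at 1 km cells ≈ the land area of the island study
    # region (~65 000 km²), which sets the granularity of NMD thinning
    n_rows: int = 250
    n_cols: int = 250
    cell_size: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    # fraction of each axis masked out in the southwest corner, emulating an
    # un-surveyed region removed from the analysis
    masked_corner_fraction: float = 0.2

    @field_validator("cell_size")
    @classmethod
    def _positive_cell(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("cell_size must be positive")
        return v

    def build(self) -> GridSpec:
        mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        kr = int(self.n_rows * self.masked_corner_fraction)
        kc = int(self.n_cols * self.masked_corner_fraction)
        if kr and kc:
            mask[:kr, :kc] = False
        return GridSpec(
            self.origin_x, self.origin_y, self.cell_size,
            self.n_rows, self.n_cols, mask,
        )


class DensityConfig(_Model):
    n_hotspots: int = 12
    hotspot_intensity: float = 200.0
    background: float = 0.5
    hotspot_sigma_cells: float = 4.0


class OccurrenceConfig(_Model):
    n_effort: int = 30000
    n_presence_target: int = 2400
    bias_strength: float = 4.0


class TruthConfig(_Model):
    intercept: float = -0.5
    coefficients: dict[str, float] = Field(
        default_factory=lambda: dict(syn_mod.default_truth().coefficients)
    )
    category_effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            k: dict(v) for k, v in syn_mod.default_truth().category_effects.items()
        }
    )


class GeneratorConfig(_Model):
    layer_specs: list[dict] = Field(default_factory=syn_mod.default_layer_specs)
    density: DensityConfig = DensityConfig()
    occurrences: OccurrenceConfig = OccurrenceConfig()
    truth: TruthConfig = TruthConfig()


class PrepConfig(_Model):
    exclusion_km: float = 3.0
    block_km: float = 5.0
    runs: int = 20
    nmd_grid: list[float] = Field(default_factory=lambda: [float(k) for k in range(1, 11)])
    parity_tolerance: float = 0.10

    @field_validator("exclusion_km")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("exclusion_km must be non-negative")
        return v


class CVConfig(_Model):
    k: int = 10
    repeats: int = 25
    selection_repeats: int = 3

    def spec(self) -> ens_mod.CVSpec:
        return ens_mod.CVSpec(self.k, self.repeats)

    def selection_spec(self) -> ens_mod.CVSpec:
        return ens_mod.CVSpec(self.k, self.selection_repeats)


class ModelConfig(_Model):
    collinearity_cutoff: float = 0.7
    variable_selection: bool = True
    selection_trees: int = 200
    fast_grids: bool = False
    suitability_threshold: float = 0.5
    rvi_permutations: int = 10
    climate_only_exclude: list[str] = Field(
        default_factory=lambda: ["land_use", "vegetation"]
    )


class ScenarioConfig(_Model):
    rcp: str = "8.5"
    year: str = "2055"
    n_gcms: int = 2
    # per-layer mean shift (standardized layer units), realised as a smooth
    # spatially varying field per GCM analogue
    deltas: dict[str, float] = Field(
        default_factory=lambda: {
            "summer_temp": 1.0,
            "summer_precip": 0.6,
            "precip_seasonality": -0.4,
            "mean_diurnal_range": -0.3,
        }
    )


def default_scenarios() -> list[ScenarioConfig]:
    half = {
        "summer_temp": 0.5,
        "summer_precip": 0.3,
        "precip_seasonality": -0.2,
        "mean_diurnal_range": -0.15,
    }
    return [
        ScenarioConfig(rcp="4.5", year="2055", deltas=half),
        ScenarioConfig(rcp="8.5", year="2055"),
    ]


class PipelineConfig(_Model):
    grid: GridConfig = GridConfig()
    generator: GeneratorConfig = GeneratorConfig()
    prep: PrepConfig = PrepConfig()
    cv: CVConfig = CVConfig()
    model: ModelConfig = ModelConfig()
    scenarios: list[ScenarioConfig] = Field(default_factory=default_scenarios)
    seed: int = 0
    output_dir: Optional[str] = None


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class RunManifest(_Model):
    model_config = ConfigDict(extra="allow")

    config_hash: str
    stages: list[str] = []
    funnel: dict[str, int] = {}
    thinning: dict = {}
    metrics: dict = {}
    selected_features: list[str] = []
    scenarios: list[dict] = []
    outputs: list[str] = []


Stage = Literal["simulate", "prep", "fit", "project", "change"]
_STAGE_ORDER = ["simulate", "prep", "fit", "project", "change"]


def run_pipeline(
    cfg: PipelineConfig,
    until: Stage = "change",
    out_dir: str | Path | None = None,
) -> RunManifest:
    """Run the pipeline through ``until`` and return the manifest."""
    stop = _STAGE_ORDER.index(until)
    out = Path(out_dir or cfg.output_dir) if (out_dir or cfg.output_dir) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg))
    seed = int(cfg.seed)

    # --- simulate -----------------------------------------------------------
    grid = cfg.grid.build()
    stack = syn_mod.generate_env_stack(grid, cfg.generator.layer_specs, seed)
    density = syn_mod.generate_density_raster(
        grid,
        cfg.generator.density.n_hotspots,
        cfg.generator.density.hotspot_intensity,
        cfg.generator.density.background,
        seed,
        cfg.generator.density.hotspot_sigma_cells,
    )
    truth = syn_mod.GeneratorTruth(
        intercept=cfg.generator.truth.intercept,
        coefficients=dict(cfg.generator.truth.coefficients),
        category_effects={
            k: dict(v) for k, v in cfg.generator.truth.category_effects.items()
        },
        seed=seed,
    )
    suit_true = syn_mod.true_suitability(stack, truth)
    occ = syn_mod.sample_occurrences(
        suit_true,
        density,
        cfg.generator.occurrences.n_presence_target,
        cfg.generator.occurrences.n_effort,
        cfg.generator.occurrences.bias_strength,
        seed,
    )
    presences_raw = occ.filter_species(syn_mod.FOCAL_SPECIES)
    background_raw = occ.filter_species(syn_mod.BACKGROUND_SPECIES)
    manifest.stages.append("simulate")
    manifest.funnel["raw_presences"] = len(presences_raw)
    manifest.funnel["raw_background"] = len(background_raw)
    log.info(
        "simulate: %d presences, %d background effort points",
        len(presences_raw), len(background_raw),
    )
    if out:
        write_stack(out / "stack_current", stack)
        write_ascii_grid(out / "human_density.asc", grid, density.values)
        write_ascii_grid(out / "true_suitability.asc", grid, suit_true.values)
        write_occurrences(out / "occurrences_raw.csv", occ)
        manifest.outputs += [
            "stack_current", "human_density.asc",
            "true_suitability.asc", "occurrences_raw.csv",
        ]
    if stop == 0:
        return _finish(manifest, out)

    # --- prep ---------------------------------------------------------------
    presences = prep_mod.grid_dedupe(presences_raw, grid)
    manifest.funnel["presences_deduped"] = len(presences)
    presences = prep_mod.filter_region(presences, grid)
    manifest.funnel["presences_in_region"] = len(presences)
    pseudo = prep_mod.make_pseudoabsences(
        background_raw, presences, grid, cfg.prep.exclusion_km
    )
    manifest.funnel["pseudoabsence_pool"] = len(pseudo)
    strat = prep_mod.stratify_density(density, grid, cfg.prep.block_km)
    target = prep_mod.compute_target_density(presences, strat)
    tcfg = prep_mod.ThinningConfig(n_runs=cfg.prep.runs, seed=seed + 1000)
    nmd_high, res_high = prep_mod.tune_nmd(
        presences, strat, "high", target, cfg.prep.nmd_grid, tcfg
    )
    nmd_low, res_low = prep_mod.tune_nmd(
        presences, strat, "low", target, cfg.prep.nmd_grid, tcfg
    )
    keep = np.sort(np.concatenate([res_low.retained, res_high.retained]))
    presences_final = presences.take(keep)
    manifest.funnel["presences_thinned"] = len(presences_final)
    balance = prep_mod.balance_pseudoabsences(
        pseudo, strat, len(presences_final), cfg.prep.nmd_grid, tcfg,
        cfg.prep.parity_tolerance,
    )
    pseudo_final = pseudo.take(balance.retained)
    manifest.funnel["pseudoabsences_balanced"] = len(pseudo_final)
    manifest.stages.append("prep")
    manifest.thinning = {
        "density_threshold": strat.threshold,
        "target_density_per_block": target,
        "nmd_presence_high": nmd_high,
        "nmd_presence_low": nmd_low,
        "presence_high": res_high.to_dict(),
        "presence_low": res_low.to_dict(),
        "nmd_pseudo_low": balance.nmd_low,
        "nmd_pseudo_high": balance.nmd_high,
        "parity_achieved": bool(balance.success),
    }
    log.info(
        "prep: NMD high=%g low=%g; %d presences, %d pseudoabsences (parity %s)",
        nmd_high, nmd_low, len(presences_final), len(pseudo_final), balance.success,
    )
    if out:
        write_occurrences(out / "presences_final.csv", presences_final)
        write_occurrences(out / "pseudoabsences_final.csv", pseudo_final)
        (out / "thinning.json").write_text(json.dumps(manifest.thinning, indent=2))
        manifest.outputs += [
            "presences_final.csv", "pseudoabsences_final.csv", "thinning.json",
        ]
    if stop == 1:
        return _finish(manifest, out)

    # --- fit ----------------------------------------------------------------
    points = OccurrenceSet(
        pd.concat(
            [presences_final.records, pseudo_final.records], ignore_index=True
        )
    )
    labels = np.r_[np.ones(len(presences_final), int), np.zeros(len(pseudo_final), int)]
    table = ens_mod.extract_features(points, labels, stack)
    table = ens_mod.drop_zero_variance(table)
    pre = ens_mod.fit_preprocessor(table)
    table_std = ens_mod.apply_preprocessor(pre, table)
    retained = ens_mod.collinearity_filter(table_std, cfg.model.collinearity_cutoff)
    if cfg.model.variable_selection and len(retained) >= 2:
        selected = ens_mod.rf_variable_selection(
            table_std.subset_features(retained),
            cfg.cv.selection_spec(),
            seed + 2000,
            n_trees=cfg.model.selection_trees,
        )
    else:
        selected = retained
    grids = ens_mod.default_tuning_grids(fast=cfg.model.fast_grids)
    ensemble = ens_mod.fit_ensemble(
        table_std, cfg.cv.spec(), grids, seed + 3000, pre, selected
    )
    auc, tss = ens_mod.model_averaged_metrics(ensemble)
    importance = ens_mod.variable_importance(
        ensemble, table_std, cfg.model.rvi_permutations, seed + 4000
    )
    current_map = proj_mod.project_map(ensemble, stack)
    area_km2, area_pct = proj_mod.suitable_area(
        current_map, cfg.model.suitability_threshold
    )
    manifest.stages.append("fit")
    manifest.selected_features = list(selected)
    manifest.metrics = {
        "collinearity_retained": retained,
        "model_averaged_auc": auc,
        "model_averaged_tss": tss,
        "member_cv_auc": {k: m.cv_auc for k, m in ensemble.members.items()},
        "member_tuned_params": {k: m.tuned_params for k, m in ensemble.members.items()},
        "rvi": importance.rvi,
        "top_rvi_feature": importance.top_feature(),
        "suitable_area_km2": area_km2,
        "suitable_area_pct": area_pct,
    }
    log.info(
        "fit: AUC=%.3f TSS=%.3f; suitable area %.0f km² (%.1f%%); top RVI %s",
        auc, tss, area_km2, area_pct, importance.top_feature(),
    )
    if out:
        write_ascii_grid(out / "suitability_current.asc", grid, current_map.values)
        (out / "evaluation.json").write_text(json.dumps(manifest.metrics, indent=2))
        manifest.outputs += ["suitability_current.asc", "evaluation.json"]
    if stop == 2:
        return _finish(manifest, out)

    # --- project + change ---------------------------------------------------
    climate_features = [
        f for f in selected if f not in cfg.model.climate_only_exclude
    ]
    climate_ens = ens_mod.fit_ensemble(
        table_std, cfg.cv.spec(), grids, seed + 3000, pre, climate_features
    )
    c_auc, c_tss = ens_mod.model_averaged_metrics(climate_ens)
    manifest.metrics["climate_only_auc"] = c_auc
    manifest.metrics["climate_only_tss"] = c_tss
    current_climate_map = proj_mod.project_map(climate_ens, stack)
    for s_idx, sc in enumerate(cfg.scenarios):
        gcm_stacks = []
        for g in range(sc.n_gcms):
            deltas = {
                name: {"magnitude": mag} for name, mag in sc.deltas.items()
            }
            gcm_stacks.append(
                syn_mod.generate_future_stack(
                    stack, deltas, seed + 5000 + 100 * s_idx + g
                )
            )
        scenario = proj_mod.ProjectionScenario(sc.rcp, sc.year, gcm_stacks)
        future_map = proj_mod.project_scenario(climate_ens, scenario)
        summary = proj_mod.change_summary(current_climate_map, future_map)
        entry = {
            "rcp": sc.rcp,
            "year": sc.year,
            "n_gcms": sc.n_gcms,
            "change": summary.to_dict(),
        }
        manifest.scenarios.append(entry)
        log.info(
            "scenario RCP %s %s: gain>5%% %.0f km², loss>5%% %.0f km², "
            "range loss at 0.5: %.0f km²",
            sc.rcp, sc.year, summary.area_gain_gt5, summary.area_loss_gt5,
            summary.range_loss_at_50,
        )
        if out:
            tag = f"rcp{sc.rcp.replace('.', '')}_{sc.year}"
            write_ascii_grid(
                out / f"suitability_{tag}.asc", grid, future_map.values
            )
            (out / f"change_{tag}.json").write_text(
                json.dumps(summary.to_dict(), indent=2)
            )
            (out / f"change_{tag}.txt").write_text(summary.to_text() + "\n")
            manifest.outputs += [
                f"suitability_{tag}.asc", f"change_{tag}.json", f"change_{tag}.txt",
            ]
    manifest.stages += ["project", "change"]
    return _finish(manifest, out)


def _finish(manifest: RunManifest, out: Path | None) -> RunManifest:
    if out:
        (out / "manifest.json").write_text(
            json.dumps(manifest.model_dump(), indent=2, sort_keys=True)
        )
    return manifest
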