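"""Raster-wide suitability projection and climate-change accounting.

Predicts the fitted ensemble over a raster stack, averages maps across
global-climate-model (GCM) analogues within an emissions scenario, measures
suitable area above a threshold, and tallies per-cell suitability change
(percentage points on the 0-100 scale) between a current and a future map:
areas gaining/losing > 0, > 5 and > 10 points, extreme changes, and range
loss at the 0.5 and 0.7 suitability thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import FeatureTable, FittedEnsemble, apply_preprocessor, predict_ensemble
from .rasters import EnvStack, SuitabilityMap


@dataclass
class ProjectionScenario:
    """A future scenario: emissions pathway, horizon year, GCM stacks."""

    rcp: str
    year: str
    gcm_stacks: list[EnvStack]

    def __post_init__(self) -> None:
        if not self.gcm_stacks:
            raise ValueError("need at least one GCM stack")
        g0 = self.gcm_stacks[0].grid
        if not all(s.grid.same_geometry(g0) for s in self.gcm_stacks):
            raise ValueError("GCM stacks must share one grid")


@dataclass
class ChangeSummary:
    """Gain/loss areas (km²) at change thresholds, extremes, and range loss."""

    area_gain_gt0: float
    area_gain_gt5: float
    area_gain_gt10: float
    area_loss_gt0: float
    area_loss_gt5: float
    area_loss_gt10: float
    max_gain_pct: float
    max_loss_pct: float
    range_loss_at_50: float
    range_loss_at_70: float
    pct_gain_gt0: float
    pct_gain_gt5: float
    pct_gain_gt10: float
    pct_loss_gt0: float
    pct_loss_gt5: float
    pct_loss_gt10: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}

    def to_text(self) -> str:
        lines = [
            f"gain > 0%:  {self.area_gain_gt0:10.1f} km²  ({self.pct_gain_gt0:5.2f}%)",
            f"gain > 5%:  {self.area_gain_gt5:10.1f} km²  ({self.pct_gain_gt5:5.2f}%)",
            f"gain > 10%: {self.area_gain_gt10:10.1f} km²  ({self.pct_gain_gt10:5.2f}%)",
            f"loss > 0%:  {self.area_loss_gt0:10.1f} km²  ({self.pct_loss_gt0:5.2f}%)",
            f"loss > 5%:  {self.area_loss_gt5:10.1f} km²  ({self.pct_loss_gt5:5.2f}%)",
            f"loss > 10%: {self.area_loss_gt10:10.1f} km²  ({self.pct_loss_gt10:5.2f}%)",
            f"max gain: {self.max_gain_pct:.1f} pct points; "
            f"max loss: {self.max_loss_pct:.1f} pct points",
            f"range change at >50% suitability: {self.range_loss_at_50:.1f} km² lost",
            f"range change at >70% suitability: {self.range_loss_at_70:.1f} km² lost",
        ]
        return "\n".join(lines)


def project_map(ens: FittedEnsemble, stack: EnvStack) -> SuitabilityMap:
    """Cellwise ensemble suitability on unmasked cells.

    The training preprocessor's center/scale is applied to the stack before
    prediction; the stack must contain every selected feature (raw scale).
    """
    missing = [n for n in ens.selected_features if n not in stack]
    if missing:
        raise KeyError(f"stack missing selected layers: {missing}")
    std = apply_preprocessor(ens.preprocessor, stack.subset(ens.selected_features))
    grid = stack.grid
    rows, cols = np.nonzero(grid.mask)
    data: dict[str, np.ndarray] = {"label": np.zeros(rows.size, dtype=int)}
    for name in ens.selected_features:
        layer = std[name]
        vals = np.asarray(layer.values)[rows, cols]
        data[name] = vals.astype(float if layer.kind == "continuous" else int)
    table = FeatureTable(pd.DataFrame(data), list(ens.continuous), dict(ens.categorical))
    preds = predict_ensemble(ens, table)
    values = np.full(grid.shape, np.nan)
    values[rows, cols] = preds
    return SuitabilityMap(grid, values)


def average_maps(maps: Sequence[SuitabilityMap]) -> SuitabilityMap:
    """Cellwise arithmetic mean across maps on one grid (GCM ensembling)."""
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one map")
    g0 = maps[0].grid
    if not all(m.grid.same_geometry(g0) for m in maps):
        raise ValueError("maps must share one grid")
    stacked = np.stack([m.values for m in maps])
    return SuitabilityMap(g0, stacked.mean(axis=0))


def project_scenario(ens: FittedEnsemble, scenario: ProjectionScenario) -> SuitabilityMap:
    """Project each GCM stack and average the resulting maps."""
    return average_maps([project_map(ens, s) for s in scenario.gcm_stacks])


def suitable_area(map_: SuitabilityMap, threshold: float) -> tuple[float, float]:
    """(km², % of unmasked area) with suitability strictly above threshold."""
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    grid = map_.grid
    vals = map_.values[grid.mask]
    n_above = int((vals > threshold).sum())
    area = n_above * grid.cell_area
    pct = 100.0 * n_above / grid.n_unmasked
    return area, pct


def change_summary(current: SuitabilityMap, future: SuitabilityMap) -> ChangeSummary:
    """Tally per-cell change Δ = (future − current) × 100 percentage points."""
    grid = current.grid
    if not grid.same_geometry(future.grid):
        raise ValueError("maps must share one grid")
    cell_area = grid.cell_area
    total = grid.n_unmasked
    delta = (future.values - current.values)[grid.mask] * 100.0

    def area_of(mask: np.ndarray) -> float:
        return float(mask.sum()) * cell_area

    def pct_of(mask: np.ndarray) -> float:
        return 100.0 * float(mask.sum()) / total

    gains = {t: delta > t for t in (0, 5, 10)}
    losses = {t: delta < -t for t in (0, 5, 10)}
    return ChangeSummary(
        area_gain_gt0=area_of(gains[0]),
        area_gain_gt5=area_of(gains[5]),
        area_gain_gt10=area_of(gains[10]),
        area_loss_gt0=area_of(losses[0]),
        area_loss_gt5=area_of(losses[5]),
        area_loss_gt10=area_of(losses[10]),
        max_gain_pct=float(delta.max()) if delta.size else 0.0,
        max_loss_pct=float(-delta.min()) if delta.size else 0.0,
        range_loss_at_50=suitable_area(current, 0.5)[0] - suitable_area(future, 0.5)[0],
        range_loss_at_70=suitable_area(current, 0.7)[0] - suitable_area(future, 0.7)[0],
        pct_gain_gt0=pct_of(gains[0]),
        pct_gain_gt5=pct_of(gains[5]),
        pct_gain_gt10=pct_of(gains[10]),
        pct_loss_gt0=pct_of(losses[0]),
        pct_loss_gt5=pct_of(losses[5]),
        pct_loss_gt10=pct_of(losses[10]),
    )
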