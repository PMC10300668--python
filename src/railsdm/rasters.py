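"""Planar raster grids, environmental layer stacks, and plain-text I/O.

All spatial data live on one planar, equal-area grid in kilometre
coordinates. A point (x, y) maps to exactly one cell via
``floor((coord - origin) / cell_size)`` with half-open cell intervals
[low, high). Rasters are written as ESRI ASCII grids (one file per layer)
with a JSON sidecar carrying layer kind and categorical level labels;
occurrence points travel as CSV with columns ``x_km,y_km,species,source``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NODATA = -9999.0

OCCURRENCE_COLUMNS = ["x_km", "y_km", "species", "source"]


@dataclass(frozen=True)
class GridSpec:
    """A rectangular analysis grid in planar km coordinates.

    Row 0 is the southernmost row (smallest y); column 0 the westernmost.
    ``mask`` is True on analysable cells.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"mask shape {mask.shape} != grid shape {(self.n_rows, self.n_cols)}"
            )
        object.__setattr__(self, "mask", mask)

    @classmethod
    def regular(
        cls,
        n_rows: int,
        n_cols: int,
        cell_size: float = 1.0,
        origin_x: float = 0.0,
        origin_y: float = 0.0,
        mask: np.ndarray | None = None,
    ) -> "GridSpec":
        if mask is None:
            mask = np.ones((n_rows, n_cols), dtype=bool)
        return cls(origin_x, origin_y, cell_size, n_rows, n_cols, mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def n_unmasked(self) -> int:
        return int(self.mask.sum())

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised point → (row, col); points off-grid get index -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def in_bounds(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, _ = self.cell_of(x, y)
        return row >= 0

    def on_unmasked(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """True where the point falls on an unmasked (analysable) cell."""
        row, col = self.cell_of(x, y)
        ok = row >= 0
        out = np.zeros(np.shape(row), dtype=bool)
        out[ok] = self.mask[row[ok], col[ok]]
        return out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and bool(np.array_equal(self.mask, other.mask))
        )


@dataclass
class EnvLayer:
    """One environmental covariate on a grid.

    Continuous layers hold float values; categorical layers hold integer
    level codes indexing ``levels``.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    values: np.ndarray
    levels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError("categorical layer requires levels")
            self.values = np.asarray(self.values)
            codes = self.values[~np.isnan(self.values.astype(float))]
            if codes.size and (codes.min() < 0 or codes.max() >= len(self.levels)):
                raise ValueError("categorical codes outside level roster")
        else:
            self.values = np.asarray(self.values, dtype=float)

    def copy(self) -> "EnvLayer":
        return EnvLayer(
            self.name,
            self.kind,
            self.values.copy(),
            list(self.levels) if self.levels else None,
        )


@dataclass
class EnvStack:
    """Named, co-registered environmental layers on one grid."""

    grid: GridSpec
    layers: dict[str, EnvLayer]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, layer in self.layers.items():
            if layer.name != name:
                raise ValueError(f"layer key {name!r} != layer.name {layer.name!r}")
            if name in seen:
                raise ValueError(f"duplicate layer name {name!r}")
            seen.add(name)
            if np.asarray(layer.values).shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape mismatch with grid")

    def __getitem__(self, name: str) -> EnvLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def continuous_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if l.kind == "continuous"]

    def categorical_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if l.kind == "categorical"]

    def subset(self, names: Iterable[str]) -> "EnvStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(self.grid, {n: self.layers[n] for n in names})

    def copy(self) -> "EnvStack":
        return EnvStack(self.grid, {n: l.copy() for n, l in self.layers.items()})


@dataclass
class SuitabilityMap:
    """Per-cell habitat suitability index in [0, 1]; NaN on masked cells."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("suitability shape mismatch with grid")
        v = self.values[self.grid.mask]
        if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("suitability values outside [0, 1]")


@dataclass
class OccurrenceSet:
    """Point records (planar km) with species and source tags."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        if not np.isfinite(df[["x_km", "y_km"]].to_numpy(dtype=float)).all():
            raise ValueError("occurrence coordinates must be finite")
        if (df["species"].astype(str).str.len() == 0).any():
            raise ValueError("species labels must be non-empty")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def x(self) -> np.ndarray:
        return self.records["x_km"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.records["y_km"].to_numpy(dtype=float)

    def xy(self) -> np.ndarray:
        return self.records[["x_km", "y_km"]].to_numpy(dtype=float)

    def take(self, indices: Sequence[int]) -> "OccurrenceSet":
        return OccurrenceSet(self.records.iloc[list(indices)].reset_index(drop=True))

    def filter_species(self, species: str) -> "OccurrenceSet":
        return OccurrenceSet(
            self.records[self.records["species"] == species].reset_index(drop=True)
        )

    @classmethod
    def from_arrays(
        cls,
        x: np.ndarray,
        y: np.ndarray,
        species: str | Sequence[str],
        source: str = "synthetic",
    ) -> "OccurrenceSet":
        n = len(np.asarray(x))
        if isinstance(species, str):
            species = [species] * n
        return cls(
            pd.DataFrame(
                {
                    "x_km": np.asarray(x, dtype=float),
                    "y_km": np.asarray(y, dtype=float),
                    "species": list(species),
                    "source": [source] * n,
                }
            )
        )


# ---------------------------------------------------------------------------
# Plain-text raster and point I/O


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    """Write one raster band as an ESRI ASCII grid (north-up row order)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    out = np.where(grid.mask & np.isfinite(values), values, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x}\n"
        f"yllcorner {grid.origin_y}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    nodata = meta.get("nodata_value", NODATA)
    mask = data != nodata
    grid = GridSpec(
        origin_x=meta["xllcorner"],
        origin_y=meta["yllcorner"],
        cell_size=meta["cellsize"],
        n_rows=int(meta["nrows"]),
        n_cols=int(meta["ncols"]),
        mask=mask,
    )
    values = np.where(mask, data, np.nan)
    return grid, values


def write_stack(directory: str | Path, stack: EnvStack) -> None:
    """Write each layer as ``<name>.asc`` plus a ``stack.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar: dict[str, dict] = {}
    for name, layer in stack.layers.items():
        write_ascii_grid(directory / f"{name}.asc", stack.grid, layer.values)
        sidecar[name] = {"kind": layer.kind, "levels": layer.levels}
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=2))


def read_stack(directory: str | Path) -> EnvStack:
    directory = Path(directory)
    sidecar = json.loads((directory / "stack.json").read_text())
    grid: GridSpec | None = None
    layers: dict[str, EnvLayer] = {}
    for name, meta in sidecar.items():
        g, values = read_ascii_grid(directory / f"{name}.asc")
        if grid is None:
            grid = g
        layers[name] = EnvLayer(name, meta["kind"], values, meta.get("levels"))
    if grid is None:
        raise ValueError(f"no layers listed in {directory / 'stack.json'}")
    return EnvStack(grid, layers)


def write_occurrences(path: str | Path, occ: OccurrenceSet) -> None:
    occ.records[OCCURRENCE_COLUMNS].to_csv(path, index=False)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    return OccurrenceSet(pd.read_csv(path))
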