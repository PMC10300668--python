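"""Bias-corrected occurrence processing.

Implements the target-group pseudoabsence design with density-stratified
spatial thinning:

1. deduplicate presences to one record per 1 km grid cell and drop records
   outside the analysis region;
2. build pseudoabsences from background (other land-bird) effort records,
   excluding any cell holding a presence and any record within the species'
   dispersal distance (default 3 km) of a presence;
3. stratify the landscape into human-density blocks (default 5 km side,
   25 km² area) classed low/high against the median block density among
   blocks with at least 1 person/km²;
4. thin each stratum with a nearest minimum-neighbour distance (NMD),
   choosing the NMD so the retained per-block density in the stratum drops
   to the level observed in low-density (least-biased) areas.

Thinning is greedy max-degree elimination with random tie-breaking, rerun
over several resampling runs keeping the run that retains the most points —
the spThin algorithm family. Distances are planar Euclidean km.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .rasters import EnvLayer, GridSpec, OccurrenceSet


@dataclass
class DensityStratification:
    """Low/high human-density classing of the landscape on coarse blocks."""

    grid: GridSpec
    block_size: float
    threshold: float
    block_high: np.ndarray  # (n_block_rows, n_block_cols) bool; True = high
    block_valid: np.ndarray  # block contains >= 1 unmasked cell

    @property
    def n_block_rows(self) -> int:
        return self.block_high.shape[0]

    @property
    def n_block_cols(self) -> int:
        return self.block_high.shape[1]

    def n_blocks(self, stratum: str) -> int:
        """Number of valid blocks in a stratum ('low' | 'high')."""
        want_high = _stratum_flag(stratum)
        return int((self.block_valid & (self.block_high == want_high)).sum())

    def block_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        bx = np.floor((np.asarray(x) - self.grid.origin_x) / self.block_size)
        by = np.floor((np.asarray(y) - self.grid.origin_y) / self.block_size)
        return by.astype(int), bx.astype(int)

    def point_stratum_mask(self, occ: OccurrenceSet, stratum: str) -> np.ndarray:
        """Boolean mask over records falling in blocks of the given class."""
        want_high = _stratum_flag(stratum)
        br, bc = self.block_of(occ.x, occ.y)
        ok = (
            (br >= 0)
            & (br < self.n_block_rows)
            & (bc >= 0)
            & (bc < self.n_block_cols)
        )
        out = np.zeros(len(occ), dtype=bool)
        idx = np.nonzero(ok)[0]
        out[idx] = self.block_high[br[idx], bc[idx]] == want_high
        return out


@dataclass
class ThinningConfig:
    nmd: float = 0.0
    n_runs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nmd < 0:
            raise ValueError("nmd must be non-negative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")


@dataclass
class ThinningResult:
    retained: np.ndarray  # indices into the input OccurrenceSet
    nmd_used: float
    runs_executed: int
    per_run_sizes: list[int]
    target_met: bool = True

    @property
    def retained_count(self) -> int:
        return len(self.retained)

    def to_dict(self) -> dict:
        return {
            "nmd_used": self.nmd_used,
            "runs_executed": self.runs_executed,
            "per_run_sizes": list(map(int, self.per_run_sizes)),
            "retained_count": self.retained_count,
            "success_flag": bool(self.target_met),
        }


@dataclass
class BalanceResult:
    """Outcome of the per-stratum NMD grid search balancing pseudoabsences."""

    retained: np.ndarray  # indices into the input pseudoabsence set
    nmd_low: float
    nmd_high: float
    success: bool
    per_pair_counts: dict[tuple[float, float], int] = field(default_factory=dict)

    @property
    def retained_count(self) -> int:
        return len(self.retained)


def _stratum_flag(stratum: str) -> bool:
    if stratum not in ("low", "high"):
        raise ValueError(f"stratum must be 'low' or 'high', got {stratum!r}")
    return stratum == "high"


# ---------------------------------------------------------------------------
# Grid deduplication and region masking


def grid_dedupe(points: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Retain one record per grid cell (the first in input order).

    Records off-grid or on masked cells are dropped.
    """
    if len(points) == 0:
        return points
    row, col = grid.cell_of(points.x, points.y)
    keep: list[int] = []
    seen: set[tuple[int, int]] = set()
    for i in range(len(points)):
        if row[i] < 0 or not grid.mask[row[i], col[i]]:
            continue
        key = (int(row[i]), int(col[i]))
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return points.take(keep)


def filter_region(points: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Drop records outside the grid extent or on masked cells; keep order."""
    if len(points) == 0:
        return points
    ok = grid.on_unmasked(points.x, points.y)
    return points.take(np.nonzero(ok)[0])


# ---------------------------------------------------------------------------
# Pseudoabsence construction


def make_pseudoabsences(
    effort: OccurrenceSet,
    presences: OccurrenceSet,
    grid: GridSpec,
    exclusion_km: float = 3.0,
) -> OccurrenceSet:
    """Target-group pseudoabsences from background effort records.

    Keeps effort records whose cell holds no presence and whose Euclidean
    distance to every presence exceeds ``exclusion_km`` (records at exactly
    the boundary distance are removed), then deduplicates to one record per
    cell (first in input order). The default 3 km is the dispersal distance
    within which the focal species can move outside its territory.
    """
    if exclusion_km < 0:
        raise ValueError("exclusion_km must be non-negative")
    effort = grid_dedupe(effort, grid)
    if len(effort) == 0:
        return effort
    if len(presences) == 0:
        return effort
    erow, ecol = grid.cell_of(effort.x, effort.y)
    prow, pcol = grid.cell_of(presences.x, presences.y)
    presence_cells = set(zip(prow.tolist(), pcol.tolist()))
    cell_free = np.array(
        [(r, c) not in presence_cells for r, c in zip(erow, ecol)], dtype=bool
    )
    tree = cKDTree(presences.xy())
    # query_ball_point with r = exclusion includes boundary-equal pairs → removed
    near = tree.query_ball_point(effort.xy(), r=exclusion_km)
    far_enough = np.array([len(nb) == 0 for nb in near], dtype=bool)
    keep = np.nonzero(cell_free & far_enough)[0]
    return effort.take(keep)


# ---------------------------------------------------------------------------
# Human-density stratification


def stratify_density(
    density: EnvLayer, grid: GridSpec, block_size: float = 5.0
) -> DensityStratification:
    """Class coarse blocks low/high against the median block density.

    Blocks are ``block_size`` km squares (default 5 km → 25 km² blocks).
    The threshold is the median of block mean densities over blocks with
    density >= 1 person/km²; a block is high iff its mean density >= the
    threshold. Sub-unit blocks (< 1 person/km²) are always low.
    """
    ratio = block_size / grid.cell_size
    if abs(ratio - round(ratio)) > 1e-9 or block_size <= 0:
        raise ValueError("block_size must be a positive multiple of cell_size")
    k = int(round(ratio))
    nbr = -(-grid.n_rows // k)
    nbc = -(-grid.n_cols // k)
    means = np.full((nbr, nbc), np.nan)
    valid = np.zeros((nbr, nbc), dtype=bool)
    vals = np.asarray(density.values, dtype=float)
    for br in range(nbr):
        for bc in range(nbc):
            sl = (slice(br * k, (br + 1) * k), slice(bc * k, (bc + 1) * k))
            m = grid.mask[sl]
            if m.any():
                valid[br, bc] = True
                means[br, bc] = vals[sl][m].mean()
    eligible = means[valid & (means >= 1.0)]
    if eligible.size == 0:
        raise ValueError("no block reaches 1 person/km²; threshold undefinable")
    threshold = float(np.median(eligible))
    high = valid & (means >= threshold) & (means >= 1.0)
    return DensityStratification(grid, float(block_size), threshold, high, valid)


def compute_target_density(
    presences: OccurrenceSet, strat: DensityStratification
) -> float:
    """Mean presence count per low-density block — the de-clustering target."""
    n_low = strat.n_blocks("low")
    if n_low == 0:
        raise ValueError("no low-density blocks")
    in_low = strat.point_stratum_mask(presences, "low")
    return float(in_low.sum()) / n_low


# ---------------------------------------------------------------------------
# NMD thinning


def _conflict_csr(points: OccurrenceSet, nmd: float):
    """CSR adjacency of the strict within-NMD conflict graph.

    Returns (indptr, indices); pairs at exactly ``nmd`` apart do not
    conflict (the retained-set contract is min distance >= nmd).
    """
    n = len(points)
    xy = points.xy()
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=nmd, output_type="ndarray")
    if pairs.size:
        # query_pairs uses dist <= r; the conflict relation is strict
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        pairs = pairs[d < nmd]
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(src, kind="stable")
    indices = dst[order]
    counts = np.bincount(src, minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return indptr, indices


def _greedy_eliminate(
    n: int, indptr: np.ndarray, indices: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Max-degree greedy elimination with uniform random tie-breaking."""
    alive = np.ones(n, dtype=bool)
    deg = np.diff(indptr).astype(np.int64)
    while True:
        dmax = deg.max() if n else 0
        if dmax <= 0:
            break
        cand = np.flatnonzero(deg == dmax)
        victim = int(cand[rng.integers(cand.size)])
        alive[victim] = False
        deg[victim] = -1
        nbrs = indices[indptr[victim] : indptr[victim + 1]]
        live = nbrs[alive[nbrs]]
        deg[live] -= 1
    return np.flatnonzero(alive)


def thin_once(points: OccurrenceSet, nmd: float, seed: int) -> np.ndarray:
    """One greedy thinning run; returns retained indices (ascending).

    While any pair lies strictly closer than ``nmd``, remove one point with
    the maximum number of such neighbours, breaking ties uniformly at random
    with the run RNG. The result has no pair closer than ``nmd`` and is
    locally maximal: no removed point can be re-added without violation.
    """
    n = len(points)
    if nmd <= 0 or n <= 1:
        return np.arange(n)
    indptr, indices = _conflict_csr(points, nmd)
    return _greedy_eliminate(n, indptr, indices, np.random.default_rng(seed))


def thin_best(points: OccurrenceSet, cfg: ThinningConfig) -> ThinningResult:
    """Repeat thinning runs and keep the run retaining the most points.

    Run ``i`` uses seed ``cfg.seed + i``; ties go to the lowest run index.
    """
    n = len(points)
    if cfg.nmd <= 0 or n <= 1:
        all_idx = np.arange(n)
        return ThinningResult(all_idx, cfg.nmd, cfg.n_runs, [n] * cfg.n_runs)
    indptr, indices = _conflict_csr(points, cfg.nmd)
    if indices.size == 0:  # no conflicts: every run retains everything
        all_idx = np.arange(n)
        return ThinningResult(all_idx, cfg.nmd, cfg.n_runs, [n] * cfg.n_runs)
    best: np.ndarray | None = None
    sizes: list[int] = []
    for i in range(cfg.n_runs):
        retained = _greedy_eliminate(
            n, indptr, indices, np.random.default_rng(cfg.seed + i)
        )
        sizes.append(len(retained))
        if best is None or len(retained) > len(best):
            best = retained
    assert best is not None
    return ThinningResult(best, cfg.nmd, cfg.n_runs, sizes)


def tune_nmd(
    points: OccurrenceSet,
    strat: DensityStratification,
    stratum: str,
    target_density: float,
    candidate_nmds: Sequence[float],
    cfg: ThinningConfig,
) -> tuple[float, ThinningResult]:
    """Pick the smallest NMD whose thinned per-block density meets the target.

    Points are restricted to blocks of the given stratum class; each
    candidate is evaluated with ``thin_best``; the retained density is
    retained count / number of valid blocks of that class. Returns the
    smallest candidate achieving density <= target (maximizing retained
    occurrences); if none does, the largest candidate with
    ``target_met=False``.
    """
    cands = list(candidate_nmds)
    if not cands:
        raise ValueError("candidate_nmds must be non-empty")
    if any(nxt <= prv for prv, nxt in zip(cands, cands[1:])):
        raise ValueError("candidate_nmds must be strictly ascending")
    mask = strat.point_stratum_mask(points, stratum)
    sub_idx = np.nonzero(mask)[0]
    if sub_idx.size == 0:
        raise ValueError(f"no points in stratum {stratum!r}")
    sub = points.take(sub_idx)
    n_blocks = strat.n_blocks(stratum)
    last: tuple[float, ThinningResult] | None = None
    for nmd in cands:
        res = thin_best(sub, ThinningConfig(nmd=nmd, n_runs=cfg.n_runs, seed=cfg.seed))
        res = ThinningResult(
            sub_idx[res.retained], nmd, res.runs_executed, res.per_run_sizes
        )
        if res.retained_count / n_blocks <= target_density:
            return float(nmd), res
        last = (float(nmd), res)
    assert last is not None
    nmd, res = last
    res.target_met = False
    return nmd, res


def balance_pseudoabsences(
    pseudo: OccurrenceSet,
    strat: DensityStratification,
    n_presence_final: int,
    candidate_nmds: Sequence[float],
    cfg: ThinningConfig,
    tolerance: float = 0.10,
) -> BalanceResult:
    """Grid-search per-stratum NMDs for presence/pseudoabsence parity.

    Thins low- and high-stratum pseudoabsences separately for every
    (nmd_low, nmd_high) candidate pair and returns the pair whose combined
    retained count is closest to ``n_presence_final`` (ties → first pair in
    ascending (low, high) order). Success iff the gap is within
    ``tolerance * n_presence_final``.
    """
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must be in (0, 1]")
    cands = list(candidate_nmds)
    if not cands:
        raise ValueError("candidate_nmds must be non-empty")
    low_idx = np.nonzero(strat.point_stratum_mask(pseudo, "low"))[0]
    high_idx = np.nonzero(strat.point_stratum_mask(pseudo, "high"))[0]
    low_pts = pseudo.take(low_idx)
    high_pts = pseudo.take(high_idx)
    if len(pseudo) <= n_presence_final:
        all_idx = np.arange(len(pseudo))
        ok = abs(len(pseudo) - n_presence_final) <= tolerance * n_presence_final
        return BalanceResult(all_idx, 0.0, 0.0, ok, {(0.0, 0.0): len(pseudo)})

    def _thin(pts: OccurrenceSet, idx: np.ndarray, nmd: float) -> np.ndarray:
        if len(pts) == 0:
            return np.array([], dtype=int)
        r = thin_best(pts, ThinningConfig(nmd=nmd, n_runs=cfg.n_runs, seed=cfg.seed))
        return idx[r.retained]

    low_cache = {nmd: _thin(low_pts, low_idx, nmd) for nmd in cands}
    high_cache = {nmd: _thin(high_pts, high_idx, nmd) for nmd in cands}
    best: BalanceResult | None = None
    best_gap = None
    counts: dict[tuple[float, float], int] = {}
    for nl, nh in itertools.product(cands, cands):
        retained = np.sort(np.concatenate([low_cache[nl], high_cache[nh]]))
        counts[(float(nl), float(nh))] = len(retained)
        gap = abs(len(retained) - n_presence_final)
        if best_gap is None or gap < best_gap:
            best_gap = gap
            best = BalanceResult(retained, float(nl), float(nh), True)
    assert best is not None and best_gap is not None
    best.success = best_gap <= tolerance * n_presence_final
    best.per_pair_counts = counts
    return best
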