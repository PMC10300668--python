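"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration, independently of
the library's implementation path.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_auc(labels: np.ndarray, predictions: np.ndarray) -> float:
    """AUC by explicit pair counting (ties count one half)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions, dtype=float)
    pos = predictions[labels == 1]
    neg = predictions[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_pseudoabsence_keep(
    effort_xy: np.ndarray,
    effort_cells: list[tuple[int, int]],
    presence_xy: np.ndarray,
    presence_cells: set[tuple[int, int]],
    exclusion_km: float,
) -> list[int]:
    """All-pairs filter: keep effort indices with no shared cell and all
    presence distances strictly greater than the exclusion radius, one per
    cell (first in order)."""
    keep = []
    seen: set[tuple[int, int]] = set()
    for i, (xy, cell) in enumerate(zip(effort_xy, effort_cells)):
        if cell in seen:
            continue
        if cell in presence_cells:
            seen.add(cell)
            continue
        d = np.sqrt(((presence_xy - xy) ** 2).sum(axis=1))
        if len(d) and d.min() <= exclusion_km:
            seen.add(cell)
            continue
        seen.add(cell)
        keep.append(i)
    return keep


def max_independent_set_size(xy: np.ndarray, nmd: float) -> int:
    """Exhaustive maximum retained-set size: largest subset with min
    pairwise distance >= nmd (conflicts are strictly closer pairs)."""
    n = len(xy)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    conflict = d < nmd
    np.fill_diagonal(conflict, False)
    for size in range(n, 0, -1):
        for subset in itertools.combinations(range(n), size):
            sub = np.array(subset)
            if not conflict[np.ix_(sub, sub)].any():
                return size
    return 0


def thinning_valid_and_maximal(
    xy: np.ndarray, retained: np.ndarray, nmd: float
) -> bool:
    """Retained set has no strictly-closer-than-nmd pair and no removed
    point could be re-added without violating the NMD."""
    retained = np.asarray(retained)
    r_xy = xy[retained]
    if len(retained) > 1:
        d = np.sqrt(((r_xy[:, None, :] - r_xy[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() < nmd:
            return False
    removed = sorted(set(range(len(xy))) - set(retained.tolist()))
    for i in removed:
        d = np.sqrt(((r_xy - xy[i]) ** 2).sum(axis=1))
        if len(d) == 0 or d.min() >= nmd:
            return False  # could be re-added: not locally maximal
    return True


def change_tally(
    current: np.ndarray, future: np.ndarray, mask: np.ndarray, cell_area: float
) -> dict:
    """Per-cell loop tally of the change-summary fields."""
    out = {
        "area_gain_gt0": 0.0, "area_gain_gt5": 0.0, "area_gain_gt10": 0.0,
        "area_loss_gt0": 0.0, "area_loss_gt5": 0.0, "area_loss_gt10": 0.0,
    }
    deltas = []
    n50_cur = n50_fut = n70_cur = n70_fut = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if not mask[i, j]:
                continue
            dlt = (future[i, j] - current[i, j]) * 100.0
            deltas.append(dlt)
            for t in (0, 5, 10):
                if dlt > t:
                    out[f"area_gain_gt{t}"] += cell_area
                if dlt < -t:
                    out[f"area_loss_gt{t}"] += cell_area
            n50_cur += current[i, j] > 0.5
            n50_fut += future[i, j] > 0.5
            n70_cur += current[i, j] > 0.7
            n70_fut += future[i, j] > 0.7
    out["max_gain_pct"] = max(deltas)
    out["max_loss_pct"] = -min(deltas)
    out["range_loss_at_50"] = (n50_cur - n50_fut) * cell_area
    out["range_loss_at_70"] = (n70_cur - n70_fut) * cell_area
    return out
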