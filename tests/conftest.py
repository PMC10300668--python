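import numpy as np
import pytest

import railsdm as r
from railsdm import ensemble as E


@pytest.fixture
def grid20() -> r.GridSpec:
    return r.GridSpec.regular(20, 20)


@pytest.fixture
def masked_grid() -> r.GridSpec:
    """10×10 grid with a masked 4×4 southwest corner."""
    mask = np.ones((10, 10), dtype=bool)
    mask[:4, :4] = False
    return r.GridSpec(0.0, 0.0, 1.0, 10, 10, mask)


def make_labelled_points(
    seed: int,
    n: int = 240,
    n_layers: int = 3,
    coefs: dict | None = None,
    grid_side: int = 40,
    category_effects: dict | None = None,
):
    """Balanced labelled points from a known suitability truth.

    Returns (table, stack, truth) with the table already standardized.
    """
    grid = r.GridSpec.regular(grid_side, grid_side)
    specs = [
        {"name": f"f{i}", "kind": "continuous", "smoothness": 2.5}
        for i in range(n_layers)
    ]
    if category_effects:
        specs.append(
            {
                "name": "land",
                "kind": "categorical",
                "smoothness": 3.0,
                "levels": list(category_effects),
            }
        )
    stack = r.generate_env_stack(grid, specs, seed)
    coefs = coefs if coefs is not None else {"f0": 2.5, "f1": 1.5}
    truth = r.GeneratorTruth(
        0.0, coefs, {"land": category_effects} if category_effects else {}
    )
    suit = r.true_suitability(stack, truth)
    rng = np.random.default_rng(seed + 17)
    rows, cols = np.nonzero(grid.mask)
    picks = rng.integers(rows.size, size=n * 12)
    p = suit.values[rows[picks], cols[picks]]
    lab = (rng.uniform(size=len(picks)) < p).astype(int)
    pos = np.flatnonzero(lab == 1)[: n // 2]
    neg = np.flatnonzero(lab == 0)[: n // 2]
    sel = np.concatenate([pos, neg])
    x = grid.origin_x + (cols[picks[sel]] + 0.5) * grid.cell_size
    y = grid.origin_y + (rows[picks[sel]] + 0.5) * grid.cell_size
    pts = r.OccurrenceSet.from_arrays(x, y, "focal_rail")
    table = E.extract_features(pts, lab[sel], stack)
    pre = E.fit_preprocessor(table)
    return E.apply_preprocessor(pre, table), stack, truth, pre


@pytest.fixture(scope="session")
def tiny_ensemble():
    """A small fitted four-member ensemble shared across tests."""
    import railsdm as r
    from railsdm import ensemble as E

    table, stack, truth, pre = make_labelled_points(seed=5, n=200)
    cv = E.CVSpec(k=5, repeats=1)
    ens = E.fit_ensemble(table, cv, E.default_tuning_grids(fast=True), 5, pre)
    return ens, table, stack
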