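"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from laminametrics import proliferation as pro
from laminametrics import synthetic as syn


def make_band_maps(preset: str, n_leaves: int, base_seed: int) -> list[syn.CellMap]:
    """Transition-zone band strips (1.0 x 0.1 mm, ~160 um^2 cells => 100-150
    cells per 200x100 um field) with GUS status from a front preset."""
    model = syn.FRONT_PRESETS[preset]
    maps = []
    for i in range(n_leaves):
        cmap = syn.gen_cell_map(1.0, 0.1, 160.0, seed=base_seed + 2 * i)
        span = pro.front_axis_span(cmap.width_um)
        maps.append(syn.assign_gus(cmap, model, seed=base_seed + 2 * i + 1, axis_span=span))
    return maps


@pytest.fixture(scope="session")
def col0_band_maps() -> list[syn.CellMap]:
    return make_band_maps("col0_like", 11, base_seed=1000)


@pytest.fixture(scope="session")
def tni_band_maps() -> list[syn.CellMap]:
    return make_band_maps("tni_like", 5, base_seed=2000)


def grid_cell_map(
    width_um: float,
    height_um: float,
    spacing_um: float = 10.0,
    gus: np.ndarray | None = None,
) -> syn.CellMap:
    """Exact regular-grid cell table (no polygons) for binning/zone tests."""
    xs = np.arange(spacing_um / 2, width_um, spacing_um)
    ys = np.arange(spacing_um / 2, height_um, spacing_um)
    xx, yy = np.meshgrid(xs, ys)
    n = xx.size
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x_um": xx.ravel(),
            "y_um": yy.ravel(),
            "area_um2": np.full(n, spacing_um**2),
            "gus": np.zeros(n, dtype=bool) if gus is None else np.asarray(gus, bool),
        }
    )
    return syn.CellMap(cells=cells, polygons=[], width_um=width_um, height_um=height_um)
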