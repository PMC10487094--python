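"""Shared fixtures: small grids and one session-scoped national model fit.

The national fit (500 presences / 500 background on a 60x80 lonlat grid,
three repeated splits) is expensive relative to everything else, so the
parameter-recovery, importance, response-curve, and warming-shift tests all
share it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import hiersdm as h
from hiersdm import synth

warnings.filterwarnings("ignore", category=FutureWarning)

NATIONAL_SEEDS = {"env": 1, "occ": 2, "thin": 3, "bg": 4, "fit": 5}


@pytest.fixture
def small_grid() -> h.GridSpec:
    """5x5 equal-area grid with 1 km cells."""
    return h.GridSpec(n_rows=5, n_cols=5, x_origin=0.0, y_origin=5000.0,
                      cell_size=1000.0)


@pytest.fixture
def lonlat_grid() -> h.GridSpec:
    """40x40 lonlat grid at 0.1 degrees, 35-39 N."""
    return h.GridSpec(n_rows=40, n_cols=40, x_origin=105.0, y_origin=39.0,
                      cell_size=0.1, crs_tag="lonlat")


def _binary(grid: h.GridSpec, values: np.ndarray, mask=None) -> h.Raster:
    return h.Raster(grid, np.asarray(values, dtype=np.int64), mask, "binary")


@pytest.fixture
def make_binary():
    return _binary


@pytest.fixture(scope="session")
def national_case():
    """Synthetic national data + fitted six-member ensemble (seed-fixed)."""
    grid = h.GridSpec(n_rows=60, n_cols=80, x_origin=97.5, y_origin=42.5,
                      cell_size=0.25, crs_tag="lonlat")
    stack = synth.make_national_environment(grid, NATIONAL_SEEDS["env"])
    truth = synth.national_truth()
    suit = synth.true_suitability(stack, truth)
    presences = h.thin_occurrences(
        synth.sample_occurrences(suit, 500, NATIONAL_SEEDS["occ"]),
        grid, NATIONAL_SEEDS["thin"],
    )
    background = h.sample_background(grid, len(presences), presences,
                                     NATIONAL_SEEDS["bg"])
    table = h.build_training_table(stack, presences, background,
                                   categorical=["lulc"])
    table = table.subset(h.select_predictors(table))
    ensemble, reports = h.fit_ensemble(table, n_runs=3,
                                       master_seed=NATIONAL_SEEDS["fit"])
    return {
        "grid": grid, "stack": stack, "truth": truth, "suitability": suit,
        "presences": presences, "background": background, "table": table,
        "ensemble": ensemble, "reports": reports,
    }
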