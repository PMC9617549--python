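"""Shared fixtures: a small synthetic world for unit tests and one full
default-conditions pipeline run shared across the integration tests."""

from __future__ import annotations

import logging

import numpy as np
import pytest

import bioturb
from bioturb import synth
from bioturb.grids import GridSpec

logging.getLogger("bioturb").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(lon_min=2.0, lon_max=4.0, lat_min=52.0, lat_max=54.0, cell_size=0.1)


@pytest.fixture(scope="session")
def small_env(small_grid):
    return synth.make_env_stack(grid=small_grid, years=[2001, 2050], warming=1.0, freshening=0.5, seed=11)


@pytest.fixture(scope="session")
def small_world(small_grid):
    """Small synthetic world (20 x 20 cells, 120 stations) for cheap unit tests."""
    return synth.make_world(grid=small_grid, years=[2001, 2050], n_stations=120, seed=11)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run under the default study conditions (fixed seed).

    Session-scoped: the integration and acceptance tests all read from this
    single run; the determinism check performs its own second run.
    """
    return bioturb.run_pipeline(bioturb.default_config(seed=1))


@pytest.fixture(scope="session")
def default_rerun():
    """Independent second run of the default conditions, for determinism checks."""
    return bioturb.run_pipeline(bioturb.default_config(seed=1))


@pytest.fixture(scope="session")
def warming_run():
    """Single-species +3 degC scenario on the cold-optimum species."""
    return bioturb.pipeline.warming_response_run(seed=1, warming_total=3.0)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[mask], b[mask])[0, 1])
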