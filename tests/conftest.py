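"""Shared fixtures: a small cold-zone cell batch equilibrated once per
session, so management/optimizer/adaptive tests reuse the same substrate."""

from __future__ import annotations

import numpy as np
import pytest

from graspasim.experiments import spinup
from graspasim.farm_optimizer import optimize_cell_batch
from graspasim.grass_growth import (
    GrassState,
    GrowthParams,
    PhotosynthesisParams,
    effective_photosynthesis_params,
    nitrogen_response,
)
from graspasim.management import ManagementParams, YearForcing
from graspasim.synthetic_forcing import generate_grid, generate_meteo


@pytest.fixture(scope="session")
def pparams() -> PhotosynthesisParams:
    return PhotosynthesisParams()


@pytest.fixture(scope="session")
def gparams() -> GrowthParams:
    return GrowthParams()


@pytest.fixture(scope="session")
def mparams() -> ManagementParams:
    return ManagementParams()


@pytest.fixture(scope="session")
def cold_cells(pparams, gparams):
    """Three cold-zone cells with one stationary forcing year, equilibrated.

    Returns (grid, [YearForcing], equilibrated GrassState).  Cold-zone cells
    have a long indoor period, keeping the optimal grazed fraction well
    below 1 so adaptive density perturbations stay in the F-adjustment
    regime.
    """
    grid = generate_grid(1, 3, seed=1, lat_range=(57.0, 60.0))
    meteo = generate_meteo(grid, 1, seed=2)
    n_add = nitrogen_response(60.0, pparams)
    vc, jm = effective_photosynthesis_params(pparams, n_add)
    forcings = [YearForcing.from_meteo(meteo, 0, 380.0, vc, jm)]
    state = GrassState.initial(grid.n_cells, shoot=800.0)
    result = spinup(state, forcings, pparams, gparams, tol=1.0, max_loops=60)
    return grid, forcings, result.state


@pytest.fixture(scope="session")
def cold_farms(cold_cells, pparams, gparams, mparams):
    """Optimal farms for the cold-zone batch (stationary forcing)."""
    _, forcings, state = cold_cells
    return optimize_cell_batch(state.copy(), forcings, pparams, gparams,
                               mparams, tol=0.02)


@pytest.fixture(scope="session")
def temperate_year(pparams):
    """A single favorable temperate forcing year for 4 cells."""
    grid = generate_grid(1, 4, seed=11, lat_range=(49.0, 52.0))
    meteo = generate_meteo(grid, 1, seed=12)
    n_add = nitrogen_response(80.0, pparams)
    vc, jm = effective_photosynthesis_params(pparams, n_add)
    return grid, YearForcing.from_meteo(meteo, 0, 380.0, vc, jm)
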