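import warnings

import numpy as np
import pytest

from hippogradients.config import RunConfig
from hippogradients.grids import make_flatmap_grid
from hippogradients.pipeline import simulate_stage, species_group_connectivity
from hippogradients.synth import make_cortex, simulate_two_species


@pytest.fixture(scope="session")
def small_grid():
    return make_flatmap_grid(8, 4)


@pytest.fixture(scope="session")
def tiny_dataset(small_grid):
    """Low-noise two-species dataset, small enough for exactness checks."""
    ch = make_cortex(40, 4, "H", 0)
    cm = make_cortex(40, 4, "M", 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_two_species(
            small_grid, ch, cm, n_subjects=3, n_timepoints=80,
            noise_sd=0.2, divergence=0.8, seed=11,
        )


@pytest.fixture(scope="session")
def default_run():
    """Default study conditions (200 parcels, 32x16 flatmap, T=600, 10
    subjects/species, unit noise, divergence 0.8) at a fixed seed, with the
    species group connectivity matrices precomputed."""
    config = RunConfig(seed=7)
    grid, ds_h, ds_m = simulate_stage(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        C_h, cleaned_h = species_group_connectivity(ds_h)
        C_m, cleaned_m = species_group_connectivity(ds_m)
    return {
        "config": config,
        "grid": grid,
        "ds_h": ds_h,
        "ds_m": ds_m,
        "C_h": C_h,
        "C_m": C_m,
        "cleaned_h": cleaned_h,
        "cleaned_m": cleaned_m,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
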