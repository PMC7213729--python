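import numpy as np
import pytest

import surveysim as ss


@pytest.fixture(scope="session")
def default_pop():
    return ss.sim_abundance(seed=1)


@pytest.fixture(scope="session")
def reduced_grid():
    """Default frame geometry at 14 km cells (20 x 20 = 400 cells)."""
    return ss.make_grid(ss.GridParams(res=(14.0, 14.0)))


@pytest.fixture(scope="session")
def reduced_spatial(default_pop, reduced_grid):
    return ss.distribute_population(default_pop, reduced_grid, seed=1)


@pytest.fixture(scope="session")
def small_survey(reduced_spatial):
    return ss.sim_survey(reduced_spatial, ss.SurveySpec(n_sims=2), seed=1)


@pytest.fixture(scope="session")
def flat_grid():
    """15 x 15 single-stratum grid with 1 km cells."""
    return ss.make_grid(ss.GridParams(
        x_range=(0, 15), y_range=(0, 15), res=(1, 1), depth_range=(0, 100),
        shelf_width=0.0, strat_breaks=(0.0, 100.0), strat_splits=0))


@pytest.fixture(scope="session")
def tiny_spatial(flat_grid):
    """Small integer-friendly population spread uniformly over flat_grid."""
    pop = ss.sim_abundance(ss.PopulationParams(
        ages=tuple(range(1, 7)), years=(1, 2, 3), mu_r=225 * 2 ** 6,
        sigma_r=0.0, mu_Z=float(np.log(2)), sigma_delta=0.0, sigma_L=0.0),
        seed=3)
    return ss.distribute_population(
        pop, flat_grid, ss.FieldParams(sd=0.0, group_ages=None),
        ss.DepthPrefParams(mu_d=50.0, sigma_d=1e9), seed=3)
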