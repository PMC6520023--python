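import warnings

import numpy as np
import pytest

from phytosdm import (
    EnvironmentConfig,
    GridSpec,
    NicheConfig,
    biased_effort,
    bin_presences,
    generate_environment,
    generate_species_pool,
    sample_occurrences,
)
from phytosdm.predictors import derive_predictors

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tiny_spec():
    return GridSpec(n_lat=14, n_lon=18, lat_min=-7.0)


@pytest.fixture(scope="session")
def tiny_env(tiny_spec):
    return generate_environment(tiny_spec, EnvironmentConfig(), seed=0)


@pytest.fixture(scope="session")
def tiny_env_derived(tiny_env):
    return derive_predictors(tiny_env)


@pytest.fixture(scope="session")
def small_world(tiny_spec, tiny_env):
    """A few Gaussian species with biased occurrence records."""
    t = tiny_env["T"].values
    t = t[np.isfinite(t)]
    pool = generate_species_pool(
        6,
        NicheConfig(
            optima={"T": (float(t.min()) + 2, float(t.max()) - 2)},
            breadths={"T": (2.5, 4.0)},
            p_max=0.4,
        ),
        seed=1,
    )
    effort = biased_effort(tiny_spec, tiny_env, seed=2)
    records = sample_occurrences(pool, tiny_env, effort, 3000, seed=3)
    return pool, records


@pytest.fixture(scope="session")
def small_presences(small_world, tiny_spec):
    _, records = small_world
    return bin_presences(records, tiny_spec)
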