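import numpy as np
import pytest

from dmpop import (
    DemographicSchedule,
    ModelConfig,
    ScenarioSpec,
    build_scenario,
    default_true_parameters,
)
from dmpop.grids import N_AGES


def make_schedule(mortality=0.0, fertility_total=0.0, migration=0.0,
                  start=2000.0, end=2040.0, srb=0.512):
    """Flat one-interval schedule; fertility_total spread evenly over 15-50."""
    fert = np.zeros((1, N_AGES))
    if fertility_total:
        fert[0, 15:51] = fertility_total / 36.0
    mort = np.full((1, N_AGES, 2), float(mortality))
    return DemographicSchedule(
        edges=np.array([start, end]), fertility=fert, mortality=mort,
        migration_edges=np.array([start, end]),
        migration=np.array([float(migration)]), sex_ratio_at_birth=srb)


@pytest.fixture(scope="session")
def zero_schedule():
    return make_schedule()


@pytest.fixture(scope="session")
def noise_free_scenario():
    """Deterministic scenario whose observations equal model expectations."""
    spec = ScenarioSpec(poisson_noise=False, binomial_noise=False, seed=7)
    return build_scenario(spec)


@pytest.fixture(scope="session")
def noisy_scenario():
    spec = ScenarioSpec(seed=11)
    return build_scenario(spec)


@pytest.fixture(scope="session")
def true_params():
    return default_true_parameters()


@pytest.fixture(scope="session")
def config():
    return ModelConfig()
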