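import numpy as np
import pytest

from asthmasim import (
    SimulationConfig,
    calibrate_all,
    default_parameter_set,
    generate_fixture_inputs,
)


@pytest.fixture(scope="session")
def params():
    return default_parameter_set()


@pytest.fixture(scope="session")
def fixture_inputs():
    """Small synthetic demographic tables shared across tests."""
    return generate_fixture_inputs(seed=0, max_age=80, years=range(2018, 2027))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        base_year=2019, horizon_end=2024, population_scale=2e-4, rng_seed=42
    )


@pytest.fixture(scope="session")
def small_calibration(fixture_inputs, params, small_config):
    return calibrate_all(
        fixture_inputs,
        params,
        list(range(small_config.base_year, small_config.horizon_end + 1)),
        min_asthma_age=small_config.min_asthma_age,
        stabilisation_year=small_config.stabilisation_year,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
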