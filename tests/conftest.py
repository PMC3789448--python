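import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from skinmaps import GAConfig, HaemoglobinTable, ParameterBounds, SpectralGrid
from skinmaps.kubelka_munk import ForwardContext

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid() -> SpectralGrid:
    return SpectralGrid.default()


@pytest.fixture(scope="session")
def table() -> HaemoglobinTable:
    return HaemoglobinTable.default()


@pytest.fixture(scope="session")
def bounds() -> ParameterBounds:
    return ParameterBounds()


@pytest.fixture(scope="session")
def ctx() -> ForwardContext:
    return ForwardContext()


@pytest.fixture(scope="session")
def generous_cfg() -> GAConfig:
    # double the standard scheme in every count: used by pipeline property
    # tests to separate the property under test from optimiser noise
    return GAConfig(
        population_size=200, iterations=100, n_best=10, n_random=50, n_cross=60, n_mutate=4
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
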