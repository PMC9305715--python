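import numpy as np
import pytest

from fruitdd import (
    DDMParameters,
    SimulationConfig,
    SourceModel,
)
from fruitdd.density import REFERENCE_N_GRID, REFERENCE_PARAMS, REFERENCE_SCENARIO
from fruitdd.synthetic import make_fixture_suite


@pytest.fixture(scope="session")
def ref_params() -> DDMParameters:
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def ref_scenario() -> SimulationConfig:
    return REFERENCE_SCENARIO


@pytest.fixture(scope="session")
def ref_n_grid() -> np.ndarray:
    return REFERENCE_N_GRID


@pytest.fixture(scope="session")
def constant_source() -> SourceModel:
    return SourceModel(mode="constant", C0=0.1)


@pytest.fixture(scope="session")
def noiseless_suite():
    """The twelve synthetic datasets without observation noise."""
    return make_fixture_suite(20240 % 2**31, noise_cv=0.0)


@pytest.fixture(scope="session")
def noisy_suite():
    """The twelve synthetic datasets at the default 10% CV noise."""
    return make_fixture_suite(77, noise_cv=0.10)
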