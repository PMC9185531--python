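import dataclasses

import numpy as np
import pytest

from glucowave.config import SimulationConfig
from glucowave.simulate import generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale campaign: 6 records per class over 3 power cycles."""
    return dataclasses.replace(
        SimulationConfig(), records_per_class=6, n_power_cycles=3
    )


@pytest.fixture(scope="session")
def small_signals(small_config):
    return generate_dataset(small_config, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
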