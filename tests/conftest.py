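import numpy as np
import pytest

from fragqc import SimulationConfig, simulate_experiment


def small_grid(n: int = 160) -> np.ndarray:
    return np.geomspace(75.0, 60_000.0, n)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced-grid copy of the default study conditions."""
    return SimulationConfig(size_grid=small_grid(), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Noise-free, jitter-free conditions for deterministic identities."""
    return SimulationConfig(
        size_grid=small_grid(400),
        noise_sd=0.0,
        size_jitter_frac=0.0,
        fish_effect_sd=0.0,
        seed=3,
    )
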