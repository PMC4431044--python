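import numpy as np
import pytest

from qgenie import SimulationConfig, simulate_ratings


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_config():
    return SimulationConfig(n_studies=12, n_raters=4, n_items=6)


@pytest.fixture
def default_ratings():
    """Default-design simulated ratings (30 studies x 4 raters x 11 items)."""
    arr, truth = simulate_ratings(SimulationConfig(), seed=7)
    return arr, truth


def full_responses(value=4, overrides=None):
    """All-11-item response map at a constant rating, with overrides."""
    resp = {i: value for i in range(1, 12)}
    resp.update(overrides or {})
    return resp
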