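from __future__ import annotations

import numpy as np
import pytest

from lensroi import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A reduced field of view and schedule for fast unit tests."""
    return SimulationConfig(
        height_px=60,
        width_px=40,
        y_range=(5, 55),
        n_pre_frames=300,
        n_post_frames=900,
        n_neurons=8,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
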