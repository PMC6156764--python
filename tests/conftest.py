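import numpy as np
import pytest

from eduscan.simulate import SimulationConfig, simulate_field


@pytest.fixture(scope="session")
def clean_small_field():
    """Noise- and background-free field: per-nucleus means are analytic."""
    cfg = SimulationConfig(
        image_shape=(256, 256),
        n_cells=40,
        touching_fraction=0.0,
        radius_sd=0.0,
        spacing_factor=4.0,
        noise_sd=0.0,
        background_amplitude=0.0,
        seed=11,
    )
    channels, truth = simulate_field(cfg)
    return cfg, channels, truth


@pytest.fixture(scope="session")
def noisy_field():
    """Default-condition field (512x512, 300 cells, 10% fused, noisy)."""
    cfg = SimulationConfig(seed=5)
    channels, truth = simulate_field(cfg)
    return cfg, channels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
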