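"""Shared fixtures: small deterministic synthetic scenes."""

import numpy as np
import pytest

from rbcbiophys.synthgen import DEFAULT_PROFILES, SceneConfig, simulate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free healthy scene with a border margin (no clipped cells)."""
    config = SceneConfig(
        field_width=200.0,
        field_height=200.0,
        n_cells=90,
        stacking_fraction=0.0,
        noise_sd=0.0,
        illumination_gradient=0.0,
        border_margin_um=8.0,
        seed=42,
    )
    pre, post, truth = simulate_scene(DEFAULT_PROFILES["healthy"], config)
    return config, pre, post, truth


@pytest.fixture(scope="session")
def stacked_scene():
    """Noise-free healthy scene with rouleaux clusters present."""
    config = SceneConfig(
        field_width=200.0,
        field_height=200.0,
        n_cells=90,
        stacking_fraction=0.1,
        noise_sd=0.0,
        illumination_gradient=0.0,
        border_margin_um=10.0,
        seed=7,
    )
    pre, post, truth = simulate_scene(DEFAULT_PROFILES["healthy"], config)
    return config, pre, post, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-condition scene: sensor noise, illumination ramp, stacking."""
    config = SceneConfig(
        field_width=200.0,
        field_height=200.0,
        n_cells=80,
        seed=3,
    )
    pre, post, truth = simulate_scene(DEFAULT_PROFILES["healthy"], config)
    return config, pre, post, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
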