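"""Shared fixtures: small synthetic instances for fast unit tests.

Unit tests run on reduced frames/cell counts for speed; the acceptance
tests exercise the full default study conditions.
"""

import numpy as np
import pytest

from imflow import GeneratorParams, PipelineConfig
from imflow.synthetic import generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_params():
    """A scaled-down generator configuration for fast unit tests."""
    return GeneratorParams(
        image_height_px=600,
        image_width_px=800,
        n_images=2,
        cells_per_image=12,
        groups={"control": 1.0, "treated": 1.3},
    )


@pytest.fixture(scope="session")
def small_experiment():
    """One small two-group experiment, shared read-only across tests."""
    params = GeneratorParams(
        image_height_px=600,
        image_width_px=800,
        n_images=2,
        cells_per_image=12,
        n_flow_events=5000,
        groups={"control": 1.0, "treated": 1.3},
    )
    return params, generate_experiment(params, seed=42)


@pytest.fixture
def small_config(small_params):
    cfg = PipelineConfig(generator=small_params)
    cfg.crop.enabled = False
    return cfg
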