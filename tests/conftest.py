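"""Shared fixtures: small labeled synthetic stands generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from forestinv.synthetic import (
    StandConfig,
    generate_regional_inventory,
    generate_stand,
    sample_stand_cloud,
)
from forestinv.terrain import classify_ground, normalize_heights


@pytest.fixture(scope="session")
def small_config() -> StandConfig:
    """A 15-tree, 30 m x 30 m stand at reduced ground density (fast)."""
    return StandConfig(seed=3, extent=(30.0, 30.0), n_trees=15, ground_density=300.0)


@pytest.fixture(scope="session")
def small_stand(small_config):
    truth = generate_stand(small_config)
    cloud = sample_stand_cloud(truth, small_config)
    return truth, cloud


@pytest.fixture(scope="session")
def small_normalized(small_stand):
    """The small stand after ground classification + height normalization."""
    _, cloud = small_stand
    return normalize_heights(classify_ground(cloud))


@pytest.fixture(scope="session")
def small_inventory(small_config):
    return generate_regional_inventory(small_config, n_plots=20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
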