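"""Shared fixtures: small, fast synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from strigacount.classical import detect_classical
from strigacount.simulate import SimConfig, simulate_dataset, simulate_image


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced assay: same object geometry, smaller disc and fewer seeds."""
    return SimConfig(
        image_size=700,
        filter_diameter=660,
        n_seeds=12,
        germination_fraction=0.5,
        radicle_length_px=(20.0, 60.0),
        debris_density=0,
        rng_seed=0,
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    return simulate_image(small_config, rng_seed=11, image_id="scene11")


@pytest.fixture(scope="session")
def small_scenes(small_config):
    scenes, manifest = simulate_dataset(small_config, 6, rng_seed=5)
    return scenes, manifest


@pytest.fixture(scope="session")
def small_scene_detections(small_scenes):
    """Unfiltered classical detections for each small scene."""
    scenes, _ = small_scenes
    return {s.annotation.image_id: detect_classical(s.image) for s in scenes}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
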