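"""Shared fixtures: small phantoms and models sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from mitoseg import (
    IntensityVolume,
    LabelVolume,
    PhantomParams,
    PipelineConfig,
    generate_phantom,
    predict_probability_map,
    sample_training_patches,
    train_patch_model,
)


SMALL_PARAMS = PhantomParams(
    shape=(14, 160, 160),
    n_organelles=3,
    organelle_axes_um=(0.2, 0.4),
    organelle_z_axes_um=(0.15, 0.3),
    vesicle_count=40,
    seed=7,
)


@pytest.fixture(scope="session")
def small_phantom() -> tuple[IntensityVolume, LabelVolume]:
    return generate_phantom(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    # fewer patch examples / trees than the study defaults: unit-test scale
    return PipelineConfig(
        n_pos_patches=300, n_neg_patches=400, rf_trees=50, seed=7
    )


@pytest.fixture(scope="session")
def small_patch_model(small_phantom, small_config):
    volume, labels = small_phantom
    ts = sample_training_patches(
        volume, labels, small_config.n_pos_patches, small_config.n_neg_patches,
        small_config.patch_size, small_config.seed,
    )
    return train_patch_model(ts, small_config.rf_trees, small_config.seed)


@pytest.fixture(scope="session")
def small_probability_map(small_phantom, small_patch_model):
    volume, _ = small_phantom
    return predict_probability_map(small_patch_model, volume)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
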