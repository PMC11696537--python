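"""Shared fixtures: small phantom datasets and (expensive) trained models, built once."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes tests/oracles.py importable

from dreamon import (
    GanConfig,
    PhantomSpec,
    TrainConfig,
    generate_phantom_dataset,
    split_dataset,
    train_classifier,
    train_image_gan,
    train_mask_gan,
)

MASTER_SEED = 20


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(n_images=130, image_size=32, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def phantom130(phantom_spec):
    return generate_phantom_dataset(phantom_spec)


@pytest.fixture(scope="session")
def splits130(phantom130):
    return split_dataset(phantom130, (90, 20, 20), seed=MASTER_SEED)


@pytest.fixture(scope="session")
def gan_config():
    return GanConfig(image_size=32, width=8, steps=200, batch_size=16, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def mask_gan(splits130, gan_config):
    train, _, _ = splits130
    masks = np.stack([s.mask for s in train])
    gen, history = train_mask_gan(masks, gan_config)
    return gen, history


@pytest.fixture(scope="session")
def image_gan(splits130, gan_config):
    train, _, _ = splits130
    gen, history = train_image_gan(train, gan_config)
    return gen, history


@pytest.fixture(scope="session")
def tiny_classifier(splits130):
    train, _, val = splits130
    config = TrainConfig(epochs=8, runs=1, arch_scale="tiny", seed=MASTER_SEED)
    return train_classifier(train, val, config)
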