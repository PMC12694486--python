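"""Shared fixtures: one synthetic dataset and one trained model per session.

The trained model uses the smallest member of the architecture family on the
schematic-face task; every saliency/metric property test reuses it.
"""

from __future__ import annotations

import numpy as np
import pytest

import fedfer as ff


@pytest.fixture(scope="session")
def synthetic_dataset() -> ff.LabeledImages:
    return ff.generate_dataset(ff.SyntheticSpec(n_per_class=500, seed=42))


@pytest.fixture(scope="session")
def synthetic_split(synthetic_dataset):
    return ff.train_test_split_synthetic(synthetic_dataset, test_fraction=0.2, seed=42)


@pytest.fixture(scope="session")
def small_arch() -> ff.ArchitectureConfig:
    return ff.ArchitectureConfig((16, 32, 64))


@pytest.fixture(scope="session")
def trained_model(synthetic_split, small_arch):
    train, test = synthetic_split
    model, _ = ff.centralized_train(
        train, small_arch, epochs=8, batch_size=64, lr=0.001, seed=42)
    acc = ff.evaluate_classification(model, test).accuracy
    assert acc >= 0.95, f"fixture model only reached {acc:.3f} test accuracy"
    return model


@pytest.fixture
def tiny_dataset() -> ff.LabeledImages:
    return ff.generate_dataset(ff.SyntheticSpec(n_per_class=16, seed=7))


@pytest.fixture
def tiny_arch() -> ff.ArchitectureConfig:
    return ff.ArchitectureConfig((2, 3, 4))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
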