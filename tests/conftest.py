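"""Shared fixtures: synthetic training data and a session-scoped trained model."""

from __future__ import annotations

import pytest

import histopat as hp


def make_balanced_patches(n_per_class: int, seed: int, crops_per_class: int = 6):
    """Class-balanced 224x224 training patches from synthetic crops."""
    crops = hp.generate_crop_set(crops_per_class, seed=seed)
    inventory = {}
    for c in crops:
        inventory.setdefault(c.label, []).append((c.width, c.height))
    plans = hp.plan_class_balancing(inventory, 224, n_per_class)
    patches = []
    for crop in crops:
        patches.extend(
            hp.extract_patches_from_crop(crop, 224, plans[crop.label].stride)
        )
    return hp.expand_dataset(patches, hp.AugmentPolicy(seed=seed), n_per_class)


@pytest.fixture(scope="session")
def small_patch_set():
    """A small labeled patch set (20/class) for fast unit tests."""
    return make_balanced_patches(20, seed=11, crops_per_class=2)


@pytest.fixture(scope="session")
def trained_model():
    """Tiny residual net trained on 200 synthetic patches per class, 6 epochs."""
    train_patches = make_balanced_patches(200, seed=5)
    config = hp.TrainConfig(depth="tiny", epochs=6, seed=0)
    model = hp.train(train_patches, config)
    return model, train_patches


@pytest.fixture(scope="session")
def dev_patch_set():
    """Held-out labeled patches from crops the training set never saw."""
    crops = hp.generate_crop_set(2, seed=99)
    dev = []
    for c in crops:
        dev.extend(hp.extract_patches_from_crop(c, 224, 224))
    return dev
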