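"""Shared fixtures: small synthetic datasets and a quickly trained classifier."""

from __future__ import annotations

import numpy as np
import pytest

from tsr_slide.classifier import TrainConfig, run_setup
from tsr_slide.datatypes import PatchSet
from tsr_slide.pipeline import normalize_patchset
from tsr_slide.stain import DEFAULT_REFERENCE
from tsr_slide.synth import SyntheticLayout, make_patch_dataset, make_slide


@pytest.fixture(scope="session")
def small_patchset() -> PatchSet:
    """60 labeled synthetic patches (20 per class), raw colors."""
    return make_patch_dataset(20, seed=11)


@pytest.fixture(scope="session")
def tiny_patchset_32() -> PatchSet:
    """Fast 32x32 labeled patches for model-selection tests."""
    return make_patch_dataset(20, seed=7, size=32)


@pytest.fixture(scope="session")
def blob_slide():
    """A mixed-class 672x672 synthetic slide with ground truth."""
    layout = SyntheticLayout.blobs(
        {"tumor": 0.38, "stroma": 0.38, "other": 0.08, "adipose": 0.06,
         "background": 0.10},
        width=672, height=672, seed=5, scale=250,
    )
    return make_slide(layout)


@pytest.fixture(scope="session")
def trained_model(small_patchset):
    """A small classifier trained quickly on normalized synthetic patches."""
    train = normalize_patchset(small_patchset, DEFAULT_REFERENCE)
    config = TrainConfig(setup="SETUP2", max_epochs=8, patience=3, seed=3)
    return run_setup("SETUP2", None, train, config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
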