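"""Shared fixtures: phantoms and a trained classifier on the compact grid.

The classifier is trained once per session on 3 phantoms; segmentation
tests evaluate on held-out phantoms generated from different seeds.
"""

import numpy as np
import pytest

from octlayers import (
    COMPACT_TEST_PROFILE,
    PhantomSpec,
    simulate_volume,
    train_from_phantoms,
)

TRAIN_SEED = 100
HELDOUT_SEEDS = (200, 201)


@pytest.fixture(scope="session")
def profile():
    return COMPACT_TEST_PROFILE


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, flat-geometry phantom: exact analytic ground truth."""
    return PhantomSpec(pit_depth_um=0.0, undulation_um=0.0,
                       speckle_shape=None, axial_blur_fwhm_um=0.0)


@pytest.fixture(scope="session")
def trained_classifier(phantom_spec, profile):
    return train_from_phantoms(phantom_spec, profile, n_phantoms=3,
                               seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def heldout_phantoms(phantom_spec, profile):
    return [simulate_volume(phantom_spec, profile, seed=s)
            for s in HELDOUT_SEEDS]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
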