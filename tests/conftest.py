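"""Shared fixtures: frequency grids, a band-coded dataset, trained models.

Training fixtures are session-scoped: several test modules (attacks,
robustness, RSA, acceptance) probe the same pair of trained fixture
classifiers rather than retraining their own.
"""

import numpy as np
import pytest

from sfprobe.frequency import build_frequency_grid
from sfprobe.pipeline import DESK_SCALE, train_model
from sfprobe.synthetic import (
    BandCodedDatasetSpec,
    generate_band_coded_dataset,
    make_fixture_classifier,
)


@pytest.fixture(scope="session")
def grid224():
    return build_frequency_grid(224, 224)


@pytest.fixture(scope="session")
def grid64():
    return build_frequency_grid(64, 64)


@pytest.fixture(scope="session")
def grid32():
    return build_frequency_grid(32, 32)


@pytest.fixture(scope="session")
def band_dataset():
    """Default band-coded set: 4 classes, 64 px, informative band [8, 16) cpi."""
    return generate_band_coded_dataset(BandCodedDatasetSpec())


@pytest.fixture(scope="session")
def band_split(band_dataset):
    """(train_x, train_y, test_x, test_y) with 150 training images per class."""
    return band_dataset.split(150)


def _train(band_split, seed):
    tr_x, tr_y, te_x, te_y = band_split
    clf = make_fixture_classifier(image_size=64, n_classes=4, seed=seed)
    log = train_model(
        clf, tr_x, tr_y, DESK_SCALE, seed=seed, val_images=te_x, val_labels=te_y
    )
    return clf, log


@pytest.fixture(scope="session")
def trained_model(band_split):
    """Fixture classifier trained on the band-coded task (seed 0)."""
    clf, log = _train(band_split, seed=0)
    assert log.val_acc[-1] > 0.9, "fixture training failed to converge"
    return clf


@pytest.fixture(scope="session")
def trained_model_b(band_split):
    """An independently initialized/trained classifier (seed 1)."""
    clf, _ = _train(band_split, seed=1)
    return clf
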