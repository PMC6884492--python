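"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from freegait import (
    GaitSimConfig,
    select_features,
    simulate_activity_windows,
    simulate_gait_recording,
    train_classifier,
)
from freegait.features import CANONICAL_FEATURES


@pytest.fixture(scope="session")
def activity_table():
    """Labelled synthetic activity-window feature table (8 subjects)."""
    return simulate_activity_windows(n_subjects=8, seed=3)


@pytest.fixture(scope="session")
def trained_model(activity_table):
    x = activity_table[list(CANONICAL_FEATURES)]
    y = activity_table.is_walking.to_numpy()
    kept = select_features(x, y)
    return train_classifier(x, y, feature_subset=kept, seed=0)


@pytest.fixture(scope="session")
def neutral_bout():
    """One simulated symmetric walking bout with its ground truth."""
    cfg = GaitSimConfig(stride_time=1.10, duty_factor=0.60, n_strides=25, seed=7)
    return simulate_gait_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
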