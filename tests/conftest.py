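"""Shared fixtures: the study dataset and one desk-scale trained model.

The desk model is trained once per session (a couple of CPU-minutes) and
shared by every test that needs a trained network.
"""

from __future__ import annotations

import numpy as np
import pytest

from echotip import segmentation as seg
from echotip import synth

STUDY_SEED = 7
DESK_SEED = 1


@pytest.fixture(scope="session")
def study_frames():
    """40 independent phantom-style frames, the standard study dataset."""
    return synth.make_study_frames(40, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_split(study_frames):
    """(train, val, test) partition of the study frames: 24 / 8 / 8."""
    return study_frames[:24], study_frames[24:32], study_frames[32:]


@pytest.fixture(scope="session")
def desk_model(study_split):
    """Desk-preset UNet trained on the augmented study training partition."""
    train_f, val_f, _ = study_split
    config = seg.desk_config(seed=DESK_SEED)
    augmented = seg.augment_dataset(train_f, config.augmentation_factor, DESK_SEED, config)
    model, history = seg.train(config, augmented, val_f)
    return {"model": model, "config": config, "history": history}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
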