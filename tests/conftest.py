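"""Shared fixtures: small synthetic sessions and a calibrated detector.

Everything is generated programmatically at fixed seeds; the session fixtures
are module-scoped because calibration on a 50-movement training record is the
most expensive shared step.
"""

import numpy as np
import pytest

from mrcploop import detector, synthetic
from mrcploop.types import GroundTruth, SyntheticConfig

PLANTED_EFFECTS = {
    ("ES", "post"): 0.1, ("PM", "post"): 0.2, ("Comb", "post"): 0.6,
    ("ES", "post30"): 0.15, ("PM", "post30"): 0.25, ("Comb", "post30"): 0.5,
}

NULL_EFFECTS = {k: 0.0 for k in PLANTED_EFFECTS}


def make_session(seed: int, n_events: int = 50, gap: float = 11.0,
                 blink_times=(), **config_kwargs):
    """A training-style session: EEG with planted MRCPs (and optional blinks)
    plus the matching EMG, with ground-truth onset times."""
    duration = n_events * gap + 20.0
    cfg = SyntheticConfig(duration=duration, seed=seed, **config_kwargs)
    onsets = 10.0 + np.arange(n_events) * gap
    eeg = synthetic.generate_background_eeg(cfg)
    eeg = synthetic.inject_mrcp(eeg, onsets, cfg)
    if len(blink_times):
        eeg = synthetic.inject_blinks(eeg, blink_times, cfg)
    emg = synthetic.generate_emg(onsets, cfg)
    return cfg, eeg, emg, onsets


@pytest.fixture(scope="session")
def training_session():
    return make_session(seed=11)


@pytest.fixture(scope="session")
def calibration(training_session):
    cfg, eeg, emg, onsets = training_session
    return detector.calibrate(eeg, onsets)


@pytest.fixture(scope="session")
def planted_truth():
    return GroundTruth(mep_effects=dict(PLANTED_EFFECTS),
                       subject_session_sd=0.3, gamma_shape=5.0)


@pytest.fixture(scope="session")
def null_truth():
    return GroundTruth(mep_effects=dict(NULL_EFFECTS),
                       subject_session_sd=0.3, gamma_shape=5.0)
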