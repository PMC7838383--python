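import numpy as np
import pytest

from neuropref.core_io import RunConfig, TrialEpoch, canonical_montage, EEGRecording
from neuropref.synthetic_eeg import SynthConfig, synth_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def canonical_epoch():
    """One deterministic 14-channel, 4 s, 128 Hz epoch."""
    r = np.random.default_rng(7)
    rec = EEGRecording(r.normal(size=(14, 512)), rate=128.0,
                       montage=canonical_montage(), subject_id="sub01")
    return TrialEpoch(rec, stimulus_id="p01_v1", subjective_label="like")


@pytest.fixture(scope="session")
def small_synth():
    """Small planted-effect dataset: 4 subjects x 12 trials, d=2."""
    cfg = SynthConfig(n_subjects=4, trials_per_subject=12, seed=11,
                      asymmetry_effect=2.0, noise_sd=0.5)
    return synth_dataset(cfg)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()
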