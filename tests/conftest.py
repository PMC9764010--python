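import numpy as np
import pytest

from eegaffect.core import EpochSet, default_montage
from eegaffect.synthetic import SimConfig, generate

FS = 128.0


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def montage():
    return default_montage()


def sine(freq, n=128, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def small_epochs(rng, montage):
    """8 trials x 14 channels x 2 s of white noise."""
    data = rng.normal(0.0, 5.0, size=(8, 14, 256))
    return EpochSet(data=data, fs=FS, channel_names=montage.channels)


@pytest.fixture(scope="session")
def clean_campaign():
    """Small synthetic campaign with a planted valence effect, no artifacts."""
    cfg = SimConfig(n_subjects=3, n_trials_per_subject=20, trial_s=2.0,
                    effects=[("F3", "alpha", "valence", 0.6)],
                    asymmetry_effects=[], motion_rate=0.0, spike_rate=0.0,
                    suppression_rate=0.0, bad_trial_rate=0.0, seed=7)
    return generate(cfg)
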