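import numpy as np
import pytest

from sbpsnn.montage import standard_montage_62
from sbpsnn.synth import SynthConfig, generate_emotion_eeg


@pytest.fixture(scope="session")
def montage():
    return standard_montage_62()


@pytest.fixture(scope="session")
def small_dataset(montage):
    """Tiny 4-class dataset with blinks, for preprocessing tests."""
    cfg = SynthConfig(n_subjects=1, n_trials_per_class=2, fs=128.0,
                      duration_s=2.0, artifact_rate=30.0, seed=11)
    return generate_emotion_eeg(cfg, montage)


@pytest.fixture(scope="session")
def clean_dataset(montage):
    """Artifact-free binary dataset for encoding/decoding tests."""
    cfg = SynthConfig(n_subjects=1, n_trials_per_class=4,
                      classes=("fear", "neutral"), fs=128.0, duration_s=1.0,
                      artifact_rate=0.0, baseline_s=0.0, coupling=[], seed=5)
    return generate_emotion_eeg(cfg, montage)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
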