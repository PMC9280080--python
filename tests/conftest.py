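import numpy as np
import pytest

from emgband import EpisodeLabels, SignalTrace, SubjectProfile, calibrate_subject, synth_episode

FS = 1100.0


@pytest.fixture(scope="session")
def default_profile():
    return SubjectProfile(seed=0)


@pytest.fixture(scope="session")
def flex_episode(default_profile):
    """1 s REST, 2 s FLEX, 1 s REST; clean; seed 0."""
    labels = EpisodeLabels.from_sequence([("REST", 1.0), ("FLEX", 2.0), ("REST", 1.0)])
    return synth_episode(default_profile, labels, None, fs=FS), labels


@pytest.fixture(scope="session")
def calibrated_stft_config(default_profile):
    return calibrate_subject(default_profile, mode="STFT_BAND", fs=FS)


@pytest.fixture(scope="session")
def calibrated_rms_config(default_profile):
    return calibrate_subject(default_profile, mode="RMS", fs=FS)


@pytest.fixture
def two_channel_trace():
    rng = np.random.default_rng(7)
    return SignalTrace(
        samples=rng.normal(size=(1100, 2)),
        fs=FS,
        channel_names=("flexor", "extensor"),
    )
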