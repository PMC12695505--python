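import numpy as np
import pytest

from qeegbands.eeg_io import EEGRecording, default_montage
from qeegbands.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


def make_recording(data, fs=512.0, labels=None, **annotations):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"Ch{i}" for i in range(data.shape[0])]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # synthetic ChN labels are not 10-20 names
        return EEGRecording(fs=fs, channels=labels, data=data, **annotations)


def sine_recording(freq_hz, fs=512.0, duration_s=8.0, n_channels=2, amplitude=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    wave = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return make_recording(np.tile(wave, (n_channels, 1)), fs=fs)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but complete synthetic cohort shared across tests."""
    config = CohortConfig(group_sizes=(4, 4, 4), fs=256.0, duration_s=8.0, seed=99)
    return generate_cohort(config)
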