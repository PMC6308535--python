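import numpy as np
import pandas as pd
import pytest

from harsel.dataset import FeatureTable, Window, segment
from harsel.synth import SubjectProfile, generate_recording


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile(subject_id=1, cadence_hz=1.8, amplitude_scale=1.0,
                          noise_sd=1.0)


@pytest.fixture(scope="session")
def walking_recording(profile):
    return generate_recording(profile, activity=3, duration_s=60, fs=80, seed=11)


@pytest.fixture(scope="session")
def walking_windows(walking_recording):
    return segment(walking_recording)


@pytest.fixture(scope="session")
def one_window(walking_windows):
    return walking_windows[0]


def make_window(channels, fs=80.0, activity=3):
    """Window wrapper around an arbitrary 6 x m array."""
    return Window(subject_id=1, activity=activity, repetition=1,
                  window_index=0, start_sample=0, fs=fs,
                  channels=np.asarray(channels, dtype=float))


def make_table(X, y, subjects=None):
    """FeatureTable from a plain matrix, with synthetic keys."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if subjects is None:
        subjects = np.zeros(len(y), dtype=int)
    keys = pd.DataFrame({
        "subject": subjects,
        "activity": y,
        "repetition": np.zeros(len(y), dtype=int),
        "window": np.arange(len(y)),
    })
    cols = [f"f{i}" for i in range(X.shape[1])]
    return FeatureTable(pd.DataFrame(X, columns=cols), y, keys)
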