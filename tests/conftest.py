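import numpy as np
import pytest

from emdhrv.preprocess import Tachogram
from emdhrv.pipeline import extract_feature_table
from emdhrv.simulate import CohortSpec, make_cohort

FS = 8.0


def make_two_tone(duration_s=300.0, a_fast=30.0, f_fast=0.25,
                  a_slow=60.0, f_slow=0.06, dc=800.0, fs=FS):
    """Tachogram-shaped two-tone signal with known generating components."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    fast = a_fast * np.sin(2 * np.pi * f_fast * t)
    slow = a_slow * np.sin(2 * np.pi * f_slow * t)
    tach = Tachogram(fs=fs, t=t, x=dc + fast + slow)
    return tach, fast, slow


@pytest.fixture
def two_tone():
    return make_two_tone()


@pytest.fixture(scope="session")
def default_cohort():
    """Paired rest/stress cohort at the default (study-condition) effect
    sizes: rest 70 bpm stationary, stress +15 bpm with halved HF
    modulation and -8% adaptation drift."""
    return make_cohort(CohortSpec(n_subjects=20, seed=1))


@pytest.fixture(scope="session")
def default_table(default_cohort):
    return extract_feature_table(default_cohort, include_band_power=True)
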