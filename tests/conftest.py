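import numpy as np
import pytest

from pushrim import AnalysisConfig, WheelGeometry, WheelTimeSeries
from pushrim.synthetic import PushProfile, TrialRecipe, generate_trial

FS = 240.0


@pytest.fixture
def geometry():
    return WheelGeometry()


@pytest.fixture
def clean_config():
    """Configuration suited to noise-free signals: no band limiting."""
    return AnalysisConfig(
        lowpass_hz=None,
        amplitude_lowpass_hz=None,
        ror_window=5,
        offset_model="none",
    )


@pytest.fixture
def noisefree_recipe():
    """Homogeneous, noise-free trial with known push parameters."""
    return TrialRecipe(
        n_pushes=8,
        profile=PushProfile(
            peak_force=100.0,
            tangential_fraction=0.35,
            push_duration=0.4,
            cycle_duration=1.2,
        ),
        push_cv={},
        noise_sd=0.0,
        ripple_amp=0.0,
        seed=0,
    )


@pytest.fixture
def noisefree_trial(noisefree_recipe):
    return generate_trial(noisefree_recipe)


def make_series(n=2400, fs=FS, side="right", **overrides):
    """Minimal valid wheel series: constant rolling, zero forces."""
    t = np.arange(n) / fs
    channels = {
        "fx": np.zeros(n),
        "fy": np.zeros(n),
        "fz": np.zeros(n),
        "mx": np.zeros(n),
        "my": np.zeros(n),
        "mz": np.zeros(n),
        "theta": 4.24 * t,
    }
    channels.update(overrides)
    return WheelTimeSeries(time=t, side=side, fs=fs, **channels)


@pytest.fixture
def rolling_series():
    return make_series()
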