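import numpy as np
import pytest

from emgrehab import calibration as cal
from emgrehab import synth_emg as se

FS = 200.0


@pytest.fixture
def default_calib() -> cal.CalibrationResult:
    """Calibration matching the default channel preset (bias 1, gain 4)."""
    return cal.CalibrationResult(bias=1.0, mve=5.0, effort_cap=0.6)


@pytest.fixture
def burst_activation():
    """Three 5 s effort bursts in 30 s, the filter-evaluation pattern."""
    schedule = [(2.5, 7.5, 1.0), (12.5, 17.5, 1.0), (22.5, 27.5, 1.0)]
    return se.make_activation(schedule, duration=30.0, fs=FS, ramp=0.25)


def single_channel_burst(seed: int, noise_sd: float, activation) -> np.ndarray:
    """One-channel raw burst trace at the default bias/gain preset."""
    chans = se.default_channels(n_channels=1, seed=seed, noise_sd=noise_sd)
    return se.synthesize_raw_emg(activation, chans).samples[:, 0]
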