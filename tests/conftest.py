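import numpy as np
import pytest
from hypothesis import settings

from sptphase import (SyntheticSpec, generate_trial, preprocess_trial)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_trial():
    """One noise-free synthetic trial with its ground truth."""
    spec = SyntheticSpec(noise_sd_N=0.0, marker_noise_sd_m=0.0, seed=11,
                         trial_id="noiseless")
    return generate_trial(spec)


@pytest.fixture(scope="session")
def noiseless_processed(noiseless_trial):
    raw, gt = noiseless_trial
    return preprocess_trial(raw), gt


@pytest.fixture(scope="session")
def noisy_trial():
    spec = SyntheticSpec(seed=12, trial_id="noisy")
    return generate_trial(spec)


@pytest.fixture(scope="session")
def noisy_processed(noisy_trial):
    raw, gt = noisy_trial
    return preprocess_trial(raw), gt


def make_processed(f_trailing=None, f_initial=None, f_target=None,
                   c7_speed=None, n=300, fs=60.0, trial_id="manual"):
    """Hand-built ProcessedTrial for detector unit tests."""
    from sptphase import ProcessedTrial

    def arr(x, fill):
        if x is None:
            return np.full(n, fill, dtype=float)
        return np.asarray(x, dtype=float)

    speed = arr(c7_speed, 0.0)
    n = len(speed)
    time = np.arange(n) / fs
    xyz = np.zeros((n, 3))
    return ProcessedTrial(
        trial_id=trial_id, time=time,
        f_trailing_hand=arr(f_trailing, 0.0)[:n],
        f_initial_seat=arr(f_initial, 0.0)[:n],
        f_target_seat=arr(f_target, 0.0)[:n],
        c7_xyz=xyz, c7_speed=speed, fs=fs,
    )
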