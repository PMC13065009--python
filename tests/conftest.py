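import numpy as np
import pytest

from oscitrack import EKFHyperParams

FS = 120.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture
def default_hp():
    """A hand-tuned, well-behaved hyperparameter set for clean signals."""
    return EKFHyperParams(q_osc=1e-2, q_freq=1e-5, q_damp=1e-5, r_meas=1e-2,
                          f_init=9.0, rho_init=0.97, p0_scale=1.0)


def tone(freq, dur_s, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t + phase)


def chirp(f0, f1, dur_s, fs=FS, amp=1.0):
    """Linear chirp with exact instantaneous-frequency ground truth."""
    n = int(dur_s * fs)
    t = np.arange(n) / fs
    f_inst = f0 + (f1 - f0) * t / dur_s
    phase = 2 * np.pi * np.cumsum(f_inst) / fs
    return amp * np.cos(phase), f_inst


@pytest.fixture
def make_tone():
    return tone


@pytest.fixture
def make_chirp():
    return chirp
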