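import numpy as np
import pytest
from scipy import signal as sps

from ppgrhythms.core import TimeSeries


def make_ar(coeffs, n, seed=0, sigma=1.0):
    """Simulate an AR process x_t = sum phi_k x_{t-k} + e_t."""
    rng = np.random.default_rng(seed)
    a = np.concatenate([[1.0], -np.asarray(coeffs, float)])
    x = sps.lfilter([1.0], a, rng.normal(0.0, sigma, n + 1000))
    return x[1000:]


def sine_ts(freq, duration, rate, amp=1.0, phase=0.0, label=""):
    t = np.arange(int(duration * rate)) / rate
    return TimeSeries(amp * np.sin(2 * np.pi * freq * t + phase), rate,
                      label=label)


@pytest.fixture(scope="session")
def baseline_recording():
    """Short two-channel baseline recording with coupling, shared by tests."""
    from ppgrhythms import synth
    p = synth.SynthParams(f_heart=1.1, f_pyloric=0.5, coupling=0.5,
                          coupling_phase_deg=190.0, noise_sd=0.1,
                          duration_s=600.0, seed=3)
    return synth.gen_baseline(p)
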