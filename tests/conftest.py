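import numpy as np
import pytest

from ppgresp import SynthConfig, TimeSeries, Window, generate_ppg


def sine_ts(freq, duration=60.0, fs=25.0, amp=1.0, phase=0.0, label=""):
    t = np.arange(0.0, duration, 1.0 / fs)
    return TimeSeries(amp * np.sin(2 * np.pi * freq * t + phase), fs, label=label)


def as_window(values, fs=25.0, j=0, start=0):
    return Window(j=j, values=np.asarray(values, dtype=float), start=start, fs=fs)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free synthetic PPG, all three respiratory mechanisms enabled."""
    return generate_ppg(SynthConfig(snr_db=np.inf, seed=11))


@pytest.fixture(scope="session")
def noisy_record():
    """10 dB synthetic PPG at the default study conditions."""
    return generate_ppg(SynthConfig(seed=11))
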