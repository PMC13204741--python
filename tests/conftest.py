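import numpy as np
import pytest

from adaptvmd import ECGSignal, NoiseSpec, SyntheticECGSpec, generate_ecg, make_noisy

FS = 360.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tone(freq_hz, fs=FS, n=2048, amp=1.0):
    t = np.arange(n) / fs
    return amp * np.sin(2.0 * np.pi * freq_hz * t)


@pytest.fixture
def clean_ecg():
    """10 s synthetic ECG at 360 Hz, 75 bpm, fixed seed."""
    return generate_ecg(SyntheticECGSpec(duration=10.0, fs=FS, heart_rate=75.0, seed=7))


@pytest.fixture
def noisy_pair(clean_ecg):
    """(clean, noisy) pair mixed to 1 dB input SNR with all three artifacts."""
    noisy, _ = make_noisy(clean_ecg, NoiseSpec(target_snr_db=1.0, seed=7))
    return clean_ecg, noisy


@pytest.fixture
def two_tone():
    """5 Hz + 40 Hz two-tone test signal, N=1024 at 360 Hz."""
    t = np.arange(1024) / FS
    x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 40 * t)
    return ECGSignal(x, FS)
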