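"""Synthetic ECG generation, the three noise archetypes, and SNR mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptvmd import (
    ECGSignal,
    InvalidSignalError,
    NoiseSpec,
    SyntheticECGSpec,
    generate_ecg,
    generate_noise,
    mix_at_snr,
    snr_db,
    welch_psd,
)

FS = 360.0


class TestSyntheticECG:
    def test_r_peak_count_matches_heart_rate(self):
        ecg = generate_ecg(SyntheticECGSpec(duration=60.0, heart_rate=75.0, rr_jitter=0.0))
        assert abs(len(ecg.annotations["r_peaks"]) - 75) <= 1

    def test_zero_jitter_gives_constant_rr(self):
        ecg = generate_ecg(SyntheticECGSpec(duration=30.0, heart_rate=80.0, rr_jitter=0.0))
        rr = np.diff(ecg.annotations["r_peaks"]) / FS
        assert np.allclose(rr, 60.0 / 80.0, atol=1.5 / FS)

    def test_same_seed_bitwise_identical(self):
        spec = SyntheticECGSpec(duration=10.0, rr_jitter=0.05, seed=42)
        a = generate_ecg(spec)
        b = generate_ecg(spec)
        assert np.array_equal(a.samples, b.samples)

    def test_low_fs_rejected(self):
        with pytest.raises(InvalidSignalError):
            generate_ecg(SyntheticECGSpec(fs=80.0))

    @pytest.mark.parametrize("kwargs", [dict(duration=0.0), dict(heart_rate=20.0),
                                        dict(heart_rate=250.0)])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(InvalidSignalError):
            SyntheticECGSpec(**kwargs)


def band_energy_fraction(x, fs, lo, hi):
    freqs, psd = welch_psd(x, fs, nperseg=min(8192, len(x)))
    total = psd.sum()
    return psd[(freqs >= lo) & (freqs <= hi)].sum() / total


class TestNoiseComponents:
    @pytest.fixture(scope="class")
    def components(self):
        return generate_noise(NoiseSpec(seed=11), n_samples=50_000, fs=FS)

    def test_drift_is_subhertz(self, components):
        n1, _, _ = components
        assert band_energy_fraction(n1, FS, 0.0, 0.5) >= 0.90
        assert band_energy_fraction(n1, FS, 1.0, FS / 2) <= 0.05

    def test_motion_fundamental_in_band(self, components):
        _, _, n3 = components
        freqs, psd = welch_psd(n3, FS, nperseg=8192)
        assert 1.0 <= freqs[np.argmax(psd)] <= 5.0

    def test_emg_without_spikes_is_gaussian(self):
        n1, n2, n3 = generate_noise(
            NoiseSpec(emg_spike_rate=0.0, seed=3), n_samples=50_000, fs=FS
        )
        d = n2 - n2.mean()
        kurt = np.mean(d**4) / np.mean(d**2) ** 2
        assert kurt == pytest.approx(3.0, abs=0.2)

    def test_spikes_fatten_the_tails(self):
        spec = dict(n_samples=50_000, fs=FS)
        _, quiet, _ = generate_noise(NoiseSpec(emg_spike_rate=0.0, seed=5), **spec)
        _, spiky, _ = generate_noise(NoiseSpec(emg_spike_rate=5.0, seed=5), **spec)
        assert np.max(np.abs(spiky)) > np.max(np.abs(quiet))

    def test_deterministic_per_seed(self):
        a = generate_noise(NoiseSpec(seed=9), 2000, FS)
        b = generate_noise(NoiseSpec(seed=9), 2000, FS)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_unit_rms_normalization(self, components):
        for comp in components:
            assert np.std(comp) == pytest.approx(1.0, rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidSignalError):
            generate_noise(NoiseSpec(), n_samples=100, fs=FS)


class TestMixAtSNR:
    @given(target=st.floats(-10.0, 20.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip_snr_exact(self, target):
        clean = generate_ecg(SyntheticECGSpec(duration=5.0, seed=2))
        comps = generate_noise(NoiseSpec(seed=2), clean.n, FS)
        noisy = mix_at_snr(clean, comps, target_snr_db=target)
        assert snr_db(clean, noisy) == pytest.approx(target, abs=1e-9)

    def test_zero_db_equal_powers(self):
        clean = generate_ecg(SyntheticECGSpec(duration=5.0, seed=2))
        comps = generate_noise(NoiseSpec(seed=2), clean.n, FS)
        noisy = mix_at_snr(clean, comps, target_snr_db=0.0)
        p_noise = np.mean((noisy.samples - clean.samples) ** 2)
        assert p_noise / np.mean(clean.samples**2) == pytest.approx(1.0, rel=1e-9)

    def test_all_zero_betas_returns_clean(self):
        clean = generate_ecg(SyntheticECGSpec(duration=5.0, seed=2))
        comps = generate_noise(NoiseSpec(seed=2), clean.n, FS)
        noisy = mix_at_snr(clean, comps, betas=(0.0, 0.0, 0.0), target_snr_db=1.0)
        assert np.array_equal(noisy.samples, clean.samples)

    def test_zero_energy_noise_rejected(self):
        clean = generate_ecg(SyntheticECGSpec(duration=5.0, seed=2))
        zeros = (np.zeros(clean.n),) * 3
        with pytest.raises(InvalidSignalError):
            mix_at_snr(clean, zeros, target_snr_db=1.0)

    def test_length_mismatch_rejected(self):
        clean = generate_ecg(SyntheticECGSpec(duration=5.0, seed=2))
        comps = (np.ones(10), np.ones(10), np.ones(10))
        with pytest.raises(InvalidSignalError):
            mix_at_snr(clean, comps, target_snr_db=1.0)
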