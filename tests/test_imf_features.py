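"""Per-mode features: PSD estimation, band ratios, kurtosis and correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from adaptvmd import (
    InvalidSignalError,
    correlation_score,
    extract_features,
    kurtosis_score,
    noise_band_complement,
    qrs_band_ratio,
    welch_psd,
)
from conftest import FS, tone


class TestWelchPSD:
    def test_tone_peak_matches_fft_oracle(self):
        freqs, psd = welch_psd(tone(10.0), FS)
        df = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(psd)] - 10.0) <= df

    def test_white_noise_is_flat(self, rng):
        x = rng.standard_normal(50_000)
        freqs, psd = welch_psd(x, FS)
        sel = (freqs >= 1.0) & (freqs <= 170.0)
        # average into 10 coarse bins; flat spectrum keeps the spread small
        chunks = np.array_split(psd[sel], 10)
        means = [c.mean() for c in chunks]
        assert max(means) / min(means) < 3.0

    def test_zero_input_zero_density(self):
        _, psd = welch_psd(np.zeros(512), FS)
        assert np.all(psd == 0)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidSignalError):
            welch_psd(np.ones(7), FS)


class TestBandRatios:
    def test_qrs_tone_in_band(self):
        assert qrs_band_ratio(tone(10.0), FS) >= 0.95

    def test_drift_tone_out_of_band(self):
        assert qrs_band_ratio(tone(0.2, n=8192), FS) <= 0.05

    def test_white_noise_band_fraction(self, rng):
        """Flat spectrum: in-band fraction ~ bandwidth ratio 15/180."""
        x = rng.standard_normal(100_000)
        assert qrs_band_ratio(x, FS) == pytest.approx(15.0 / 180.0, abs=0.03)

    def test_noise_complement_tone_outside_noise_bands(self):
        assert noise_band_complement(tone(10.0), FS) >= 0.95

    @pytest.mark.parametrize("freq", [45.0, 0.5])
    def test_noise_complement_tone_inside_noise_bands(self, freq):
        assert noise_band_complement(tone(freq, n=8192), FS) <= 0.05

    def test_zero_power_mode_scores_zero(self):
        assert qrs_band_ratio(np.zeros(512), FS) == 0.0
        assert noise_band_complement(np.zeros(512), FS) == 0.0

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(4096)
        assert qrs_band_ratio(5.0 * x, FS) == pytest.approx(qrs_band_ratio(x, FS), rel=1e-9)
        assert noise_band_complement(5.0 * x, FS) == pytest.approx(
            noise_band_complement(x, FS), rel=1e-9
        )


def moment_kurtosis(x):
    """Oracle: plain moment-ratio kurtosis m4 / m2^2."""
    d = x - x.mean()
    return np.mean(d**4) / np.mean(d**2) ** 2


class TestKurtosisScore:
    def test_exact_mesokurtic_sequence_scores_one(self):
        x = np.array([-1.0, 1.0, 0.0, 0.0, 0.0, 0.0])  # m4/m2^2 = 3 exactly
        assert moment_kurtosis(x) == pytest.approx(3.0)
        assert kurtosis_score(x) == pytest.approx(1.0)

    def test_closed_form_against_moment_oracle(self, rng):
        x = rng.standard_normal(500) ** 3  # heavy-tailed
        k = moment_kurtosis(x)
        assert kurtosis_score(x) == pytest.approx(1.0 / (1.0 + abs(k - 3.0)), rel=1e-9)

    def test_sinusoid_kurtosis(self):
        # sinusoid kurtosis -> 1.5, score -> 1/(1+1.5) = 0.4
        assert kurtosis_score(tone(7.0, n=36000)) == pytest.approx(0.4, abs=0.02)

    def test_zero_variance_scores_zero(self):
        assert kurtosis_score(np.full(100, 2.0)) == 0.0


class TestCorrelationScore:
    def test_identity_and_sign_symmetry(self, clean_ecg):
        assert correlation_score(clean_ecg.samples, clean_ecg) == pytest.approx(1.0)
        assert correlation_score(-clean_ecg.samples, clean_ecg) == pytest.approx(1.0)

    def test_orthogonal_signals(self):
        n = 3600
        t = np.arange(n) / FS
        assert correlation_score(np.sin(2 * np.pi * 5 * t), np.cos(2 * np.pi * 5 * t)) <= 0.02

    def test_constant_input_scores_zero(self, clean_ecg):
        assert correlation_score(np.ones(clean_ecg.n), clean_ecg) == 0.0

    def test_length_mismatch_rejected(self, clean_ecg):
        with pytest.raises(InvalidSignalError):
            correlation_score(np.ones(10), clean_ecg)


@given(
    x=hnp.arrays(
        np.float64,
        st.integers(64, 256),
        elements=st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False),
    )
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_all_features_normalized_to_unit_interval(x):
    """Contract: every feature lies in [0, 1] for any finite input."""
    ref = np.sin(np.arange(x.size) * 0.3)
    score = extract_features(x, FS, ref)
    for v in score.as_tuple():
        assert 0.0 <= v <= 1.0
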