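"""Per-IMF features used to tell ECG-bearing modes from noise-bearing ones.

Four features, each normalized to [0, 1]:

* ``s_qrs``   — fraction of Welch PSD energy in the QRS band [5, 20] Hz;
* ``s_noise`` — one minus the PSD fraction in the drift ([0, 1] Hz) and
  EMG ([30, 60] Hz) noise bands;
* ``s_kurt``  — 1 / (1 + |kurtosis - 3|): modes near Gaussianity (noise)
  score low-ish, strongly non-Gaussian ECG modes score higher;
* ``s_corr``  — |Pearson r| between the mode and the decomposition input.

Welch PSDs use a Hamming window with 50% overlap; see ``welch_psd`` for the
segment-length choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np
from scipy import signal as sps

from .signals import ConfigurationError, ECGSignal, InvalidSignalError, as_samples


@dataclass
class SpectralBands:
    """Frequency bands (Hz) used by the spectral features. The QRS complex
    concentrates its energy in roughly [5, 20] Hz; baseline/motion drift
    sits below 1 Hz and EMG interference above 30 Hz."""

    qrs_band: tuple[float, float] = (5.0, 20.0)
    drift_band: tuple[float, float] = (0.0, 1.0)
    emg_band: tuple[float, float] = (30.0, 60.0)

    def __post_init__(self) -> None:
        for name in ("qrs_band", "drift_band", "emg_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name} must satisfy lower < upper")
            if lo < 0:
                raise ConfigurationError(f"{name} must be nonnegative")

    def validate_against_fs(self, fs: float) -> None:
        for name in ("qrs_band", "drift_band", "emg_band"):
            if getattr(self, name)[1] > fs / 2:
                raise ConfigurationError(f"{name} exceeds the Nyquist frequency {fs / 2}")


DEFAULT_BANDS = SpectralBands()


@dataclass
class IMFScore:
    """Feature vector of one mode plus (once weighted) its composite score."""

    s_qrs: float
    s_noise: float
    s_corr: float
    s_kurt: float
    composite: float = nan
    mode_index: int = -1

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.s_qrs, self.s_noise, self.s_corr, self.s_kurt)


def welch_psd(
    mode: np.ndarray, fs: float, nperseg: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD with a Hamming window and 50% overlap.

    The segment length defaults to ``min(1024, N)``: at wearable sampling
    rates (125-500 Hz) this gives sub-hertz bin spacing, which is required to
    resolve the [0, 1] Hz drift band against its neighbors.
    """
    x = as_samples(mode)
    if x.size < 8:
        raise InvalidSignalError(f"mode too short for PSD estimation ({x.size} < 8)")
    if nperseg is None:
        nperseg = min(1024, x.size)
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
    )
    return freqs, psd


def _band_power_fraction(
    freqs: np.ndarray, psd: np.ndarray, bands: list[tuple[float, float]]
) -> float | None:
    """PSD fraction in the union of ``bands`` (bin membership by bin center,
    both endpoints included). None when total power is zero."""
    total = psd.sum()
    if total <= 0:
        return None
    mask = np.zeros(freqs.size, dtype=bool)
    for lo, hi in bands:
        mask |= (freqs >= lo) & (freqs <= hi)
    return float(psd[mask].sum() / total)


def qrs_band_ratio(
    mode: np.ndarray, fs: float, bands: SpectralBands = DEFAULT_BANDS
) -> float:
    """Fraction of the mode's power in the QRS band; 0 for a zero-power mode."""
    freqs, psd = welch_psd(mode, fs)
    frac = _band_power_fraction(freqs, psd, [bands.qrs_band])
    if frac is None:
        return 0.0
    return float(np.clip(frac, 0.0, 1.0))


def noise_band_complement(
    mode: np.ndarray, fs: float, bands: SpectralBands = DEFAULT_BANDS
) -> float:
    """One minus the power fraction inside the drift and EMG bands; 0 for a
    zero-power mode (a silent mode carries no ECG content)."""
    freqs, psd = welch_psd(mode, fs)
    frac = _band_power_fraction(freqs, psd, [bands.drift_band, bands.emg_band])
    if frac is None:
        return 0.0
    return float(np.clip(1.0 - frac, 0.0, 1.0))


def kurtosis_score(mode: np.ndarray) -> float:
    """1 / (1 + |K - 3|) with the biased moment-ratio kurtosis (3 for normal
    data); equals 1 iff the sample kurtosis is exactly 3.  Zero-variance
    modes return 0 by convention."""
    x = as_samples(mode)
    d = x - x.mean()
    s = np.sqrt(np.mean(d**2))
    if s == 0:
        return 0.0
    # standardize before the fourth moment so tiny amplitudes cannot underflow
    k = float(np.mean((d / s) ** 4))
    return 1.0 / (1.0 + abs(k - 3.0))


def correlation_score(mode: np.ndarray, original: ECGSignal | np.ndarray) -> float:
    """|Pearson r| between the mode and the decomposition input, clipped to
    [0, 1].  The absolute value guards against solver sign flips.  Constant
    input on either side returns 0."""
    x = as_samples(mode)
    y = as_samples(original)
    if x.size != y.size:
        raise InvalidSignalError("mode and original must have equal lengths")
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    xs = (x - x.mean()) / np.std(x)
    ys = (y - y.mean()) / np.std(y)
    r = float(np.mean(xs * ys))
    if not np.isfinite(r):
        return 0.0
    return float(np.clip(abs(r), 0.0, 1.0))


def extract_features(
    mode: np.ndarray,
    fs: float,
    original: ECGSignal | np.ndarray,
    bands: SpectralBands = DEFAULT_BANDS,
    mode_index: int = -1,
) -> IMFScore:
    """Compute all four features for one mode (composite left unset)."""
    bands.validate_against_fs(fs)
    return IMFScore(
        s_qrs=qrs_band_ratio(mode, fs, bands),
        s_noise=noise_band_complement(mode, fs, bands),
        s_corr=correlation_score(mode, original),
        s_kurt=kurtosis_score(mode),
        mode_index=mode_index,
    )
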