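"""Denoising evaluation metrics: SNR / dSNR, MSE, RMSE, PRD, Pearson rho, RTR.

All reference-based metrics compare an estimate against the known clean
signal.  SNR and PRD are linked by SNR_dB = 20*log10(100 / PRD%) for the
same pair, a useful cross-check.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .signals import ECGSignal, InvalidSignalError, as_samples

#: Sentinel returned when the error energy is exactly zero (estimate equals
#: the reference): benchmark tables stay numeric instead of crashing or
#: propagating infinities.  Reports carry ``snr_saturated`` flags.
SNR_INF_DB = 300.0


@dataclass
class MetricsReport:
    snr_raw_db: float
    snr_denoised_db: float
    delta_snr_db: float
    mse: float
    rmse: float
    prd: float
    correlation: float
    rtr: float | None = None
    elapsed_s: float | None = None
    snr_saturated: bool = False


def _pair(reference, estimate) -> tuple[np.ndarray, np.ndarray]:
    ref = as_samples(reference)
    est = as_samples(estimate)
    if ref.size != est.size:
        raise InvalidSignalError("reference and estimate must have equal lengths")
    return ref, est


def snr_db(reference: ECGSignal | np.ndarray, estimate: ECGSignal | np.ndarray) -> float:
    """10*log10(reference energy / error energy).

    An estimate identical to the reference returns the :data:`SNR_INF_DB`
    sentinel rather than raising or overflowing.
    """
    ref, est = _pair(reference, estimate)
    e_ref = float(np.sum(ref**2))
    if e_ref == 0:
        raise InvalidSignalError("reference has zero energy")
    e_err = float(np.sum((est - ref) ** 2))
    if e_err == 0:
        return SNR_INF_DB
    return float(10.0 * np.log10(e_ref / e_err))


def delta_snr_db(
    clean: ECGSignal | np.ndarray,
    noisy: ECGSignal | np.ndarray,
    denoised: ECGSignal | np.ndarray,
) -> float:
    """SNR improvement: snr(clean, denoised) - snr(clean, noisy)."""
    return snr_db(clean, denoised) - snr_db(clean, noisy)


def error_metrics(
    reference: ECGSignal | np.ndarray, estimate: ECGSignal | np.ndarray
) -> tuple[float, float, float]:
    """Return (MSE, RMSE, PRD%): mean squared error, its square root, and the
    root error energy relative to the reference energy as a percent."""
    ref, est = _pair(reference, estimate)
    err = est - ref
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    e_ref = float(np.sum(ref**2))
    if e_ref == 0:
        raise InvalidSignalError("PRD undefined for a zero-energy reference")
    prd = float(np.sqrt(np.sum(err**2) / e_ref) * 100.0)
    return mse, rmse, prd


def correlation(
    reference: ECGSignal | np.ndarray, estimate: ECGSignal | np.ndarray
) -> float:
    """Pearson correlation coefficient in [-1, 1]; morphology fidelity."""
    ref, est = _pair(reference, estimate)
    if np.std(ref) == 0 or np.std(est) == 0:
        raise InvalidSignalError("correlation undefined for a constant signal")
    return float(np.clip(np.corrcoef(ref, est)[0, 1], -1.0, 1.0))


def rtr(signal_duration_s: float, processing_time_s: float) -> float:
    """Real-time ratio: signal duration / processing time (> 1 means faster
    than real time). Hardware-dependent; reported, never asserted on."""
    if not signal_duration_s > 0 or not processing_time_s > 0:
        raise InvalidSignalError("duration and processing time must both be positive")
    return signal_duration_s / processing_time_s


def evaluate(
    clean: ECGSignal,
    noisy: ECGSignal | np.ndarray,
    denoised: ECGSignal | np.ndarray,
    elapsed_s: float | None = None,
) -> MetricsReport:
    """Assemble the full metric bundle for one denoising run."""
    s_raw = snr_db(clean, noisy)
    s_den = snr_db(clean, denoised)
    mse, rmse, prd = error_metrics(clean, denoised)
    rho = correlation(clean, denoised)
    ratio = None
    if elapsed_s is not None and elapsed_s > 0:
        ratio = rtr(clean.duration_s, elapsed_s)
    return MetricsReport(
        snr_raw_db=s_raw,
        snr_denoised_db=s_den,
        delta_snr_db=s_den - s_raw,
        mse=mse,
        rmse=rmse,
        prd=prd,
        correlation=rho,
        rtr=ratio,
        elapsed_s=elapsed_s,
        snr_saturated=(s_raw >= SNR_INF_DB or s_den >= SNR_INF_DB),
    )


class Timer:
    """Context manager measuring wall-clock processing time for RTR."""

    def __enter__(self) -> "Timer":
        self._t0 = time.perf_counter()
        self.elapsed_s = 0.0
        return self

    def __exit__(self, *exc) -> None:
        self.elapsed_s = time.perf_counter() - self._t0
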