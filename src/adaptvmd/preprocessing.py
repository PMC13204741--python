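"""Conditioning chain applied before decomposition.

Three stages, in order: a second-order Butterworth high-pass at 0.5 Hz
(baseline drift), a 0.5-40 Hz Butterworth band-pass (the clinically
effective ECG band), and a powerline notch (50 Hz by default; North-American
recordings such as MIT-BIH need 60 Hz).  Filters run forward-backward by
default so QRS timing is not delayed; a causal single-pass mode exists for
streaming use.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.signal import butter, filtfilt, iirnotch, lfilter, sosfilt, sosfiltfilt

from .signals import ECGSignal, InvalidSignalError


@dataclass
class PreprocessConfig:
    hp_cutoff: float = 0.5
    hp_order: int = 2
    bp_band: tuple[float, float] = (0.5, 40.0)
    # overall band-pass order; realized as butter(order/2, band)
    bp_order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0
    zero_phase: bool = True


def preprocess(signal: ECGSignal, config: PreprocessConfig | None = None) -> ECGSignal:
    """Apply high-pass, band-pass and notch in that order; length preserved.

    Raises :class:`InvalidSignalError` when the sampling rate cannot carry
    the configured bands (fs must exceed twice the band-pass upper edge and
    the notch frequency must sit below Nyquist).
    """
    config = config or PreprocessConfig()
    fs = signal.fs
    if fs <= 2 * max(config.bp_band):
        raise InvalidSignalError(
            f"fs={fs} too low for band-pass {config.bp_band} (need fs > {2 * max(config.bp_band)})"
        )
    if config.notch_freq >= fs / 2:
        raise InvalidSignalError(f"notch frequency {config.notch_freq} above Nyquist")

    sos_hp = butter(config.hp_order, config.hp_cutoff, "highpass", fs=fs, output="sos")
    sos_bp = butter(
        max(config.bp_order // 2, 1), config.bp_band, "bandpass", fs=fs, output="sos"
    )
    b_notch, a_notch = iirnotch(config.notch_freq, config.notch_q, fs=fs)

    y = signal.samples
    if config.zero_phase:
        y = sosfiltfilt(sos_hp, y)
        y = sosfiltfilt(sos_bp, y)
        y = filtfilt(b_notch, a_notch, y)
    else:
        y = sosfilt(sos_hp, y)
        y = sosfilt(sos_bp, y)
        y = lfilter(b_notch, a_notch, y)
    return ECGSignal(y, fs, label=signal.label, annotations=dict(signal.annotations))
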