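"""Core signal container and error types shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np


class InvalidSignalError(ValueError):
    """Raised when a signal (or signal-derived argument) violates a precondition."""


class ConfigurationError(ValueError):
    """Raised when a configuration object is internally inconsistent."""


@dataclass
class ECGSignal:
    """A uniformly sampled single-channel ECG trace.

    Parameters
    ----------
    samples : array-like of float
        Amplitude sequence (mV or arbitrary units, passed through untouched).
    fs : float
        Sampling rate in Hz. Must be positive.
    label : str, optional
        Free-text provenance tag (record name, generator spec, ...).
    annotations : dict, optional
        Auxiliary markers, e.g. ``{"r_peaks": ndarray of sample indices}``.
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    annotations: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 2:
            raise InvalidSignalError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidSignalError("signal contains non-finite samples")
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise InvalidSignalError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def copy(self, **changes: Any) -> "ECGSignal":
        out = replace(self, **changes)
        out.samples = np.array(out.samples, dtype=float, copy=True)
        return out


def as_samples(signal: "ECGSignal | np.ndarray") -> np.ndarray:
    """Return the raw sample array of an :class:`ECGSignal` or array-like."""
    if isinstance(signal, ECGSignal):
        return signal.samples
    return np.asarray(signal, dtype=float).ravel()
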