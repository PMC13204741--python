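"""Seeded synthetic ECG and motion-noise generation.

The noisy signal model is

    s_noisy(t) = s_clean(t) + sum_i beta_i * n_i(t),  i = 1..3

with three archetypal wearable-ECG disturbances:

* ``n1`` — low-frequency baseline drift, a sum of three sinusoids with
  random frequencies in [0.05, 0.5] Hz (respiration / electrode motion);
* ``n2`` — EMG interference: broadband white Gaussian noise plus sparse
  20 ms biphasic spikes of random polarity (sudden muscle bursts);
* ``n3`` — quasi-periodic limb-motion artifact: a 1-5 Hz sinusoid
  amplitude-modulated by a slow 0.2 Hz raised-cosine envelope, mimicking
  intermittent rhythmic movement.

Each component is normalized to unit RMS before weighting so the ``betas``
act as interpretable relative intensities; the combined noise is then
rescaled by one global factor to hit the requested input SNR exactly.

The clean-ECG generator is the standard sum-of-Gaussians beat template:
five Gaussian bumps (P, Q, R, S, T) repeated at the configured heart rate,
with optional fractional RR jitter.  All generators are pure functions of
their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import ConfigurationError, ECGSignal, InvalidSignalError

#: Per-wave (amplitude mV, center offset s relative to the R peak, width s)
#: of the default beat template.
DEFAULT_MORPHOLOGY: dict[str, tuple[float, float, float]] = {
    "P": (0.15, -0.20, 0.025),
    "Q": (-0.10, -0.035, 0.010),
    "R": (1.20, 0.0, 0.012),
    "S": (-0.25, 0.035, 0.010),
    "T": (0.35, 0.30, 0.060),
}

#: Modulation frequency (Hz) of the limb-motion envelope.
MOTION_ENVELOPE_HZ = 0.2


@dataclass
class SyntheticECGSpec:
    duration: float = 10.0
    fs: float = 360.0
    heart_rate: float = 75.0
    rr_jitter: float = 0.0
    beat_morphology: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise InvalidSignalError("duration must be positive")
        if not 30 <= self.heart_rate <= 220:
            raise InvalidSignalError("heart_rate must lie in [30, 220] bpm")
        if self.rr_jitter < 0:
            raise InvalidSignalError("rr_jitter must be nonnegative")


@dataclass
class NoiseSpec:
    betas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    drift_band: tuple[float, float] = (0.05, 0.5)
    emg_spike_rate: float = 1.0
    motion_band: tuple[float, float] = (1.0, 5.0)
    target_snr_db: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.betas) != 3 or any(b < 0 for b in self.betas):
            raise ConfigurationError("betas must be 3 nonnegative weights")
        for name in ("drift_band", "motion_band"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi:
                raise ConfigurationError(f"{name} must be an ordered nonnegative band")
        if self.emg_spike_rate < 0:
            raise ConfigurationError("emg_spike_rate must be nonnegative")


def generate_ecg(spec: SyntheticECGSpec) -> ECGSignal:
    """Generate a quasi-periodic PQRST train; deterministic per seed.

    R-peak sample indices are attached as ``annotations["r_peaks"]``.
    Sampling rates below 100 Hz cannot resolve the beat morphology and are
    rejected.
    """
    if spec.fs < 100:
        raise InvalidSignalError(f"fs={spec.fs} < 100 Hz cannot resolve PQRST morphology")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    rr0 = 60.0 / spec.heart_rate

    r_times = [0.3]
    while True:
        rr = rr0 * (1.0 + spec.rr_jitter * float(rng.standard_normal()))
        rr = max(rr, 0.3 * rr0)
        nxt = r_times[-1] + rr
        if nxt >= spec.duration:
            break
        r_times.append(nxt)

    x = np.zeros(n)
    half_span = 0.5  # each beat's waves live within +-0.5 s of the R peak
    for tr in r_times:
        i0 = max(int((tr - half_span) * spec.fs), 0)
        i1 = min(int((tr + half_span) * spec.fs) + 1, n)
        tw = t[i0:i1]
        for amp, center, width in spec.beat_morphology.values():
            x[i0:i1] += amp * np.exp(-((tw - tr - center) ** 2) / (2.0 * width**2))

    r_peaks = np.array([int(round(tr * spec.fs)) for tr in r_times])
    r_peaks = r_peaks[r_peaks < n]
    return ECGSignal(
        x, spec.fs, label=f"synthetic-ecg(seed={spec.seed})", annotations={"r_peaks": r_peaks}
    )


def generate_noise(
    spec: NoiseSpec, n_samples: int, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate the three noise components, each normalized to unit RMS.

    Requires at least one second of samples so the drift band is resolvable.
    """
    if n_samples < fs:
        raise InvalidSignalError("need at least 1 s of samples to synthesize noise")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n_samples) / fs

    # n1: baseline drift — three random sinusoids inside the drift band
    f_drift = rng.uniform(*spec.drift_band, size=3)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
    amp = rng.uniform(0.5, 1.0, size=3)
    n1 = np.sum(
        amp[:, None] * np.sin(2.0 * np.pi * f_drift[:, None] * t + phase[:, None]), axis=0
    )
    n1 /= np.std(n1)

    # n2: EMG — white Gaussian floor plus sparse biphasic spikes
    n2 = rng.standard_normal(n_samples)
    n_spikes = rng.poisson(spec.emg_spike_rate * n_samples / fs)
    spike_len = max(int(round(0.02 * fs)), 2)
    pulse = np.sin(2.0 * np.pi * np.arange(spike_len) / spike_len)  # one biphasic cycle
    for _ in range(n_spikes):
        start = int(rng.integers(0, n_samples - spike_len + 1))
        magnitude = rng.uniform(3.0, 6.0) * rng.choice((-1.0, 1.0))
        n2[start : start + spike_len] += magnitude * pulse
    n2 /= np.std(n2)

    # n3: limb motion — slow raised-cosine envelope on a 1-5 Hz carrier
    f_motion = rng.uniform(*spec.motion_band)
    phase3 = rng.uniform(0.0, 2.0 * np.pi)
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * MOTION_ENVELOPE_HZ * t))
    n3 = envelope * np.sin(2.0 * np.pi * f_motion * t + phase3)
    n3 /= np.std(n3)

    return n1, n2, n3


def mix_at_snr(
    clean: ECGSignal,
    components: tuple[np.ndarray, np.ndarray, np.ndarray],
    betas: tuple[float, float, float] = (1.0, 1.0, 1.0),
    target_snr_db: float = 1.0,
) -> ECGSignal:
    """Add the beta-weighted noise, globally rescaled so the mixture's input
    SNR equals ``target_snr_db`` exactly.

    All-zero betas are the infinite-SNR convention: the clean signal is
    returned unchanged.
    """
    if all(b == 0 for b in betas):
        return clean.copy(label="noisy(snr=inf)")
    noise = np.zeros_like(clean.samples)
    for beta, comp in zip(betas, components):
        comp = np.asarray(comp, dtype=float)
        if comp.size != clean.n:
            raise InvalidSignalError("noise component length differs from clean signal")
        noise += beta * comp
    p_clean = float(np.mean(clean.samples**2))
    p_noise = float(np.mean(noise**2))
    if p_clean == 0:
        raise InvalidSignalError("clean signal has zero energy")
    if p_noise == 0:
        raise InvalidSignalError("combined noise has zero energy with a finite SNR target")
    scale = np.sqrt(p_clean / (p_noise * 10.0 ** (target_snr_db / 10.0)))
    return ECGSignal(
        clean.samples + scale * noise,
        clean.fs,
        label=f"noisy(snr={target_snr_db}dB)",
        annotations=dict(clean.annotations),
    )


def make_noisy(
    clean: ECGSignal, spec: NoiseSpec
) -> tuple[ECGSignal, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Convenience: synthesize the three components for ``clean`` and mix at
    the spec's target SNR. Returns (noisy, components)."""
    components = generate_noise(spec, clean.n, clean.fs)
    noisy = mix_at_snr(clean, components, spec.betas, spec.target_snr_db)
    return noisy, components
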