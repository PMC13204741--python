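"""Composite IMF scoring and the adaptive threshold/floor/ceiling selection.

Each mode's four features are fused into a single score

    S_k = 0.4*S_qrs + 0.3*S_noise + 0.2*S_corr + 0.1*S_kurt

(default weights from an offline analytic-hierarchy-process derivation;
spectral content dominates).  Selection then applies:

1. adaptive threshold  s_th = max(0.15, 0.8 * median(S_k)); keep S_k >= s_th;
2. floor — if fewer than 2 survive, forcibly keep the top 3 (all if K < 3);
3. ceiling — if more than 4 survive, keep only the top 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan
from typing import Sequence

import numpy as np

from .core_vmd import IMFSet
from .imf_features import DEFAULT_BANDS, IMFScore, SpectralBands, extract_features
from .signals import ConfigurationError, ECGSignal, InvalidSignalError


@dataclass
class SelectionPolicy:
    """Weights and decision constants of the mode-selection stage.

    Weight order is (qrs, noise, corr, kurt); they must be nonnegative and
    sum to 1.  ``abs_threshold`` is the absolute score floor, and the
    relative threshold is ``rel_threshold_factor`` times the median score.
    """

    weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    abs_threshold: float = 0.15
    rel_threshold_factor: float = 0.8
    floor_count: int = 3
    ceiling_count: int = 4
    min_selected: int = 2

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size != 4 or np.any(w < 0):
            raise ConfigurationError("weights must be 4 nonnegative reals")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"weights must sum to 1, got {w.sum()!r}")
        if not 0 < self.rel_threshold_factor <= 1:
            raise ConfigurationError("rel_threshold_factor must be in (0, 1]")
        if self.floor_count > self.ceiling_count:
            raise ConfigurationError("floor_count must not exceed ceiling_count")


#: Alternate weight presets evaluated in the parameter study: AHP-derived
#: default, uniform, and reversed importance order.
WEIGHT_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "ahp": (0.4, 0.3, 0.2, 0.1),
    "uniform": (0.25, 0.25, 0.25, 0.25),
    "reversed": (0.1, 0.2, 0.3, 0.4),
}


@dataclass
class SelectionResult:
    """Scores, the threshold actually used, the retained mode indices
    (ascending) and which rule produced them (threshold/floor/ceiling, or
    ``fixed`` for the non-adaptive baseline)."""

    scores: list[IMFScore] = field(default_factory=list)
    threshold_used: float = float("nan")
    selected_indices: list[int] = field(default_factory=list)
    rule_applied: str = "threshold"


def composite_score(features: IMFScore, policy: SelectionPolicy | None = None) -> float:
    """Weighted sum of the four features under ``policy.weights``."""
    policy = policy or SelectionPolicy()
    return float(np.dot(policy.weights, features.as_tuple()))


def score_modes(
    imfs: IMFSet,
    original: ECGSignal | np.ndarray,
    bands: SpectralBands = DEFAULT_BANDS,
    policy: SelectionPolicy | None = None,
) -> list[IMFScore]:
    """Feature-score every mode of a decomposition against the input signal,
    filling in the composite score."""
    policy = policy or SelectionPolicy()
    scores = []
    for k in range(imfs.K):
        sc = extract_features(imfs.modes[k], imfs.fs, original, bands, mode_index=k)
        sc.composite = composite_score(sc, policy)
        scores.append(sc)
    return scores


def _composites(scores: Sequence[IMFScore | float]) -> np.ndarray:
    vals = [s.composite if isinstance(s, IMFScore) else float(s) for s in scores]
    return np.asarray(vals, dtype=float)


def select_imfs(
    scores: Sequence[IMFScore | float], policy: SelectionPolicy | None = None
) -> SelectionResult:
    """Apply the threshold/floor/ceiling rules to composite scores.

    ``scores`` may be plain floats or scored :class:`IMFScore` records.
    Ties at a floor/ceiling cut are broken toward the lower mode index
    (lower center frequency).
    """
    policy = policy or SelectionPolicy()
    vals = _composites(scores)
    K = vals.size
    if K == 0:
        raise InvalidSignalError("empty score list")

    threshold = max(policy.abs_threshold, policy.rel_threshold_factor * float(np.median(vals)))
    passed = [i for i in range(K) if vals[i] >= threshold]
    by_score = sorted(range(K), key=lambda i: (-vals[i], i))

    if len(passed) < policy.min_selected:
        count = K if K < 3 else min(policy.floor_count, K)
        selected = by_score[:count]
        rule = "floor"
    elif len(passed) > policy.ceiling_count:
        selected = sorted(passed, key=lambda i: (-vals[i], i))[: policy.ceiling_count]
        rule = "ceiling"
    else:
        selected = passed
        rule = "threshold"

    score_records = [
        s if isinstance(s, IMFScore) else IMFScore(nan, nan, nan, nan, composite=float(s), mode_index=i)
        for i, s in enumerate(scores)
    ]
    return SelectionResult(
        scores=score_records,
        threshold_used=float(threshold),
        selected_indices=sorted(selected),
        rule_applied=rule,
    )
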