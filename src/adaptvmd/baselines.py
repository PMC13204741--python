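"""Fixed-parameter VMD baseline for head-to-head comparison.

The conventional recipe: decompose with fixed K = 8, alpha = 2000 and keep
the first four modes — interpreted here as the four of lowest center
frequency after ascending sort, since ECG energy concentrates at low
frequencies and raw solver ordering is initialization-dependent.  No
adaptive threshold, no noise-aware alpha, no post-smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_vmd import VMDConfig, decompose
from .imf_selection import SelectionResult
from .reconstruction import DenoisingResult, reconstruct
from .signals import ECGSignal, InvalidSignalError


@dataclass
class TraditionalVMDPolicy:
    K: int = 8
    alpha: float = 2000.0
    n_keep: int = 4

    def __post_init__(self) -> None:
        if self.n_keep > self.K:
            raise InvalidSignalError("n_keep must not exceed K")


def traditional_vmd_denoise(
    signal: ECGSignal, policy: TraditionalVMDPolicy | None = None
) -> DenoisingResult:
    """Denoise by summing the ``n_keep`` lowest-frequency modes of a
    fixed-parameter decomposition."""
    policy = policy or TraditionalVMDPolicy()
    if signal.n < 16:
        raise InvalidSignalError("signal too short for the fixed-parameter baseline")
    config = VMDConfig(K=policy.K, alpha=policy.alpha)
    imfs = decompose(signal, config)
    selection = SelectionResult(
        scores=[],
        threshold_used=float("nan"),
        selected_indices=list(range(policy.n_keep)),
        rule_applied="fixed",
    )
    denoised = reconstruct(imfs, selection, smooth=False)
    return DenoisingResult(
        denoised=denoised,
        selection=selection,
        imfs=imfs,
        config_used=config,
        noise_assessment=None,
    )
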