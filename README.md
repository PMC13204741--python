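# adaptvmd

Adaptive variational mode decomposition (VMD) for removing motion artifacts
from single-channel wearable ECG.

Wearable ECG recordings made during daily activity are contaminated by
baseline drift (respiration and electrode motion, ≈0.05–0.5 Hz), broadband
electromyographic (EMG) interference with sudden spike bursts, and
quasi-periodic limb-motion artifacts (1–5 Hz) whose spectra overlap the ECG
itself. `adaptvmd` separates these from the cardiac signal by decomposing
each segment into narrow-band intrinsic mode functions (IMFs) and keeping
only the modes that look like ECG. It is aimed at people building ECG
pipelines — denoising before R-peak detection, ST analysis, or beat
classification — and at anyone who wants a self-contained, testable VMD
implementation with an explicit mode-selection rule.

## Method

VMD solves

```
min_{u_k, ω_k}  Σ_k ‖ ∂_t [ (δ(t) + j/(πt)) * u_k(t) ] e^{-jω_k t} ‖²₂
s.t.            Σ_k u_k(t) = x(t)   (relaxed; penalty weight α)
```

by ADMM in the frequency domain, yielding K band-limited modes u_k with
center frequencies ω_k. On top of the plain solver, the pipeline adapts
itself to the segment:

1. **Length-adaptive parameters** — K = 6, α = 1000 for segments shorter
   than 1000 samples; K = 8, α = 1500 otherwise.
2. **Noise-aware bandwidth penalty** — a robust noise scale
   σ = median(|x − median x|)/0.6745 is compared against θ = 0.5·std(x);
   when σ > θ, α is inflated by 1 + log₂(1 + σ/θ).
3. **Multi-feature mode selection** — each IMF is scored

   ```
   S_k = 0.4·S_qrs + 0.3·S_noise + 0.2·S_corr + 0.1·S_kurt
   ```

   where S_qrs is the Welch-PSD power fraction in the QRS band [5, 20] Hz,
   S_noise is one minus the fraction in the noise bands [0, 1] ∪ [30, 60] Hz,
   S_corr = |Pearson r| against the input, and S_kurt = 1/(1 + |K_kurt − 3|).
   Modes with S_k ≥ max(0.15, 0.8·median S_k) are kept, with a floor
   (top 3 if fewer than 2 pass) and a ceiling (top 4 if more than 4 pass).
4. **Reconstruction** — the selected modes are summed and smoothed with a
   quadratic Savitzky–Golay filter (window ≈ 10 ms, forced odd, minimum 5).

A fixed-parameter baseline (K = 8, α = 2000, keep the 4 lowest-frequency
modes, no smoothing) is included for comparison, together with the metric
suite SNR/ΔSNR, MSE, RMSE, PRD, Pearson ρ and the real-time ratio RTR, and
a seeded simulator that generates clean PQRST trains plus the three noise
archetypes mixed to an exact target input SNR.

## Worked example

```
$ adaptvmd --seed 1 simulate --duration 10 --snr-db 1 --out-dir . --prefix demo
wrote demo_clean.csv / demo_noisy.csv (3600 samples) to .

$ adaptvmd denoise --input demo_noisy.csv --format csv \
      --output demo_denoised.csv --no-preprocess
denoised 3600 samples -> demo_denoised.csv (K=8, selected=[1, 2, 5, 7])

$ adaptvmd metrics --clean demo_clean.csv --noisy demo_noisy.csv \
      --denoised demo_denoised.csv
{
  "correlation": 0.8753758341253636,
  "delta_snr_db": 2.9020775121554037,
  ...
  "prd": 63.81108430370165,
  "snr_raw_db": 1.0000000000000002
}
```

The 10 s synthetic recording is mixed to exactly 1 dB input SNR; the
adaptive pipeline picks K = 8, retains 4 of the 8 modes, and improves SNR by
2.9 dB while keeping correlation with the clean reference at 0.875 — the
noise modes (drift near DC, EMG above 30 Hz) are dropped, the QRS-band modes
kept. The sidecar `demo_denoised.sidecar.json` records every resolved
parameter (seed, K, α, σ, θ, threshold, selected modes) so the run can be
reproduced exactly.

The same comparison over several seeds:

```
$ adaptvmd --seed 0 benchmark --n-seeds 5 --duration 10 --out bench.csv
improved_vmd: mean dSNR = 2.75 dB, mean correlation = 0.860
traditional_vmd: mean dSNR = 1.30 dB, mean correlation = 0.736
```

The adaptive selection consistently beats the fixed keep-the-lowest-four
rule, which cannot drop the drift-dominated lowest mode.

Library use mirrors the CLI:

```python
from adaptvmd import SyntheticECGSpec, NoiseSpec, generate_ecg, make_noisy
from adaptvmd import denoise_adaptive, evaluate

clean = generate_ecg(SyntheticECGSpec(duration=10, seed=1))
noisy, _ = make_noisy(clean, NoiseSpec(target_snr_db=1.0, seed=1))
result = denoise_adaptive(noisy)
print(evaluate(clean, noisy, result.denoised))
```

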