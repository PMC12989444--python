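# ppgdenoise

Motion-artifact removal for dual-wavelength photoplethysmography (PPG),
built for synchronously sampled red (660 nm) / infrared (940 nm) channel
pairs from reflective wrist sensors.

Wrist PPG is the workhorse of wearable heart-rate monitoring, but motion
artifacts (MA) from sensor–skin movement share the 0.5–5 Hz band with the
cardiac pulse, so no fixed frequency-selective filter can remove them.
When both wavelengths are acquired strictly simultaneously, the artifact
appears in both channels with near-identical waveform (it is the same
mechanical perturbation), while the arterial pulsation appears with a
different amplitude ratio. `ppgdenoise` exploits exactly that structure —
no accelerometer or gyroscope required.

## Method

With the mixing model

```
x1 = a·AC + c·MA          (red)
x2 =   AC +   MA          (infrared)
```

each 8-s frame is processed in four stages:

1. **Blind source separation.** The weighted difference `S(n) = x1 − c·x2`
   is passed through a single-tap predictor at the arterial period `Ta`
   (from the autocorrelation peak in the 40–180 bpm lag range), and
   `(c, b)` minimize the prediction-error variance
   `J(c,b) = E[(S(n) − b·S(n−Ta))²]`. Because AC is periodic at `Ta` and
   MA is not, the minimum cancels the artifact from `S`, driving `c` to
   the artifact's inter-channel ratio. The arterial-removal coefficient
   `α = E[x1·S]/E[S²]` then yields `β = α·c/(α−1)`, and
   `N(n) = x1 − β·x2` is a **noise reference**: strongly correlated with
   the artifact, nearly orthogonal to the pulse.
2. **Entropy gating.** The power spectral entropy
   `H = −Σ pᵢ·log2(pᵢ + ε)` of the frame (sub-band-aggregated periodogram
   over 0.5–5 Hz) classifies it as weak (`H ≤ HT`) or strong (`H > HT`)
   interference, with `HT = 2` bits.
3. **Mode-switched, grid-searched LMS.** The reference drives an FIR
   adaptive filter `y(n) = Wᵀu(n)`, `e(n) = x2(n) − y(n)`,
   `W ← W + μ·e(n)·u(n)`, with `(μ, N)` searched exhaustively inside the
   mode's grid — soft (μ ∈ [3e-4, 7e-4], N ∈ [25, 50]) for weak frames,
   hard (μ ∈ [8e-4, 1.5e-3], N ∈ [51, 120]) for strong frames — to
   minimize the error-signal entropy `He`. The cleaned frame is `e(n)`.
4. **Heart-rate evaluation.** Systolic peaks of the cleaned signal give
   windowed HR (60 / mean inter-beat interval per 8-s window), compared
   with a reference by Pearson `R`, mean absolute error, and Bland–Altman
   limits of agreement `[μ − 1.96σ, μ + 1.96σ]`.

Because real dual-wavelength recordings with ground truth are scarce, the
package ships a calibrated simulator (`ppgdenoise.synthwave`) producing
recordings with known AC, MA, mixing ratios, and instantaneous heart
rate, including the rest/swing acquisition protocol (3 × [10 s rest +
16 s arm swing]) used for validation.

## Worked example

```python
from ppgdenoise import (denoise_recording, protocol_swing, detect_peaks,
                        hr_series, hr_reference_series)
from ppgdenoise.hrmetrics import agreement_report, paired_valid

rec = protocol_swing(seed=42)          # 78 s, 1000 Hz, with ground truth
result = denoise_recording(rec)

strong = sum(fr.mode == "strong" for fr in result.frames)
print(f"{len(result.frames)} frames, {strong} strong-interference")

fs = rec.fs
est = hr_series(detect_peaks(result.cleaned, fs), fs, window_s=8.0,
                total_s=result.cleaned.size / fs)
ref = hr_reference_series(rec.truth.hr_trace, fs, window_s=8.0)
e, r = paired_valid(est, ref)
rep = agreement_report(e, r)
print(f"HR agreement over {rep.n_pairs} windows: "
      f"MAE = {rep.MAE:.2f} bpm, bias = {rep.bias_mu:+.2f} bpm, "
      f"LOA = [{rep.loa_low:.2f}, {rep.loa_high:.2f}] bpm")
```

prints

```
10 frames, 9 strong-interference
HR agreement over 10 windows: MAE = 0.38 bpm, bias = +0.15 bpm, LOA = [-0.77, 1.06] bpm
```

The artifact dominates nine of the ten frames (the protocol is mostly
swing once frames straddle segment boundaries), yet the windowed heart
rate recovered from the cleaned signal stays within a fraction of a beat
per minute of the generator's truth; the same recording evaluated raw is
off by roughly 10–15 bpm. Per-frame diagnostics are on each
`FrameResult`: e.g. the first (rest) frame has entropy 0.83 bits → weak
mode, while frame 2 has 2.63 bits → strong mode, where the grid search
settled on (μ*, N*) = (0.0015, 70) with a cleaned-frame entropy of 1.72
bits.

The same pipeline is available from the shell:

```
ppgdenoise simulate --seed 42 --out rec.csv
ppgdenoise denoise  --in rec.csv --out cleaned.csv --diag frames.jsonl
ppgdenoise evaluate --est cleaned.csv --ref rec.csv --out report.json
```

`simulate` writes the recording with ground-truth columns; `evaluate`
accepts either a recording with a truth `hr` column or a `beat_s` CSV of
reference beat times (aligned by peak-train cross-correlation). All
parameters live in one YAML config (see `ppgdenoise.config`); every
command is bit-reproducible for a fixed seed.

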