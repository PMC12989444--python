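# Methods

This note records the model assumptions, the estimation and filtering
procedures, every tunable that matters, and the reasoning behind design
choices that were genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal model and assumptions

Two PPG channels are assumed synchronously sampled (same clock, no
inter-channel lag) at a known rate `fs` (1000 Hz default):

    x1(n) = a·AC(n) + c·MA(n) + d1(n) + w1(n)     (red, 660 nm)
    x2(n) =   AC(n) +   MA(n) + d2(n) + w2(n)     (infrared, 940 nm)

- `AC` — arterial pulsation, quasi-periodic with instantaneous period
  `Ta` in the 40–180 bpm range; statistically independent of `MA`.
- `MA` — motion artifact, broadband inside the cardiac band
  (0.5–5 Hz), *identical waveform in both channels* up to the scalar
  ratio `c` (the consequence of strictly simultaneous acquisition
  through a shared optical path), and nearly unpredictable at lag `Ta`.
- `d` — baseline drift below the 0.5 Hz low cut; `w` — white sensor
  noise. Both are removed or negligible after band-pass conditioning.

The method degrades gracefully when these assumptions weaken: a less
correlated artifact pair lowers the achievable reference purity; an
artifact with a strong periodic component near `Ta` biases the period
estimate (mitigated by the two-probe search below).

## Synthetic data generator

Real dual-wavelength recordings with per-sample ground truth are not
available, so validation runs on a generator that embodies the model:

- **Pulse**: a phase integrator driven by the per-sample heart-rate
  trace, with three decaying harmonics (amplitudes 1.0/0.4/0.2),
  zero-mean, unit peak. This gives well-defined periodicity and one
  dominant peak per beat. It does *not* reproduce real pulse morphology
  (dicrotic notch, respiratory amplitude modulation, beat-to-beat HRV),
  so passing tests demonstrate algorithmic correctness under the model,
  not clinical performance.
- **Artifact**: 4th-order Butterworth (0.5–5 Hz) filtered white noise
  plus one sinusoid per motion burst at a randomized swing frequency
  (0.8–2 Hz), scaled to a target SD, zero outside bursts with 0.5 s
  cosine edge tapers. ≥ 95 % of its power lies in-band, i.e. it overlaps
  the cardiac band completely — the regime the method targets.
- **Protocol scenario**: 3 cycles of 10 s rest + 16 s swing (78 s),
  HR 75 ± 3 bpm drifting slowly, mixing ratios a = 0.5, c = 2.0,
  artifact SD 2.0 (≈ 3.6× the pulse SD — strong interference), channel
  noise SD 0.05, drift 0.2 at ≤ 0.2 Hz. The ratios are placeholders —
  neither is known for real skin — and are configurable.
- **Canonical estimation frame**: a single fully contaminated 8-s frame
  with broadband-only MA at SD 0.15 and noise SD 0.01, used by the
  estimation batteries (see "β error scaling" below for why this SD).

All randomness flows from one master seed through spawned
`SeedSequence` streams; identical (config, seed) pairs are
byte-identical after serialization.

## Preprocessing

Each channel is normalized to [−1, 1] over the whole recording, then
band-passed 0.5–5 Hz with a 4th-order Butterworth prototype (8-pole
band-pass) applied causally in second-order sections. The causal filter
is warm-started over an odd-reflected pre-extension of `3/lo` seconds
(discarded from the output): the 0.5 Hz pole otherwise rings for
several seconds and masquerades as broadband content in the first
frame. Zero-phase (forward–backward) filtering is available but off by
default. Frames are 8 s, non-overlapping; a final partial frame is kept
iff ≥ 4 s (the period search needs ≥ 3 s at the 40 bpm lag bound).

Note the per-channel normalization rescales the mixing ratios: the
pipeline estimates `c` and `β` *of the normalized pair*, which differ
from the generator's `a, c` by the ratio of the channel scales. This is
irrelevant downstream (the reference and the filter are scale-free);
recovery of the generator's ratios is validated on unnormalized frames.

## BSS estimation, per frame

**Period.** `Ta` is the arg-max of the lag-wise cosine similarity
(autocorrelation normalized by the energies of the two overlapping
segments) over lags in the 40–180 bpm range, accepted if the peak
reaches 0.15. The cosine normalization attains exactly 1 at the true
period of an exactly periodic signal, unlike the biased estimator whose
lag taper shifts the peak. The pipeline searches two probes — `x2`, and
the motion-cancelled combination `S0 = x1 − c0·x2` with `c0` the
least-squares projection — and keeps the stronger peak: `x2` wins on
clean frames (where `S0` contains no arterial content by construction),
`S0` wins when the artifact buries the pulse. If neither yields a peak:
previous frame's `Ta`, else a 75 bpm prior. After fitting `c`, the
period is refined once on the arterial estimate `S = x1 − c·x2`.

**(c, b) fit.** Exact alternating least squares on
`J(c,b) = E[(S(n) − b·S(n−Ta))²]`: given `c`,
`b = E[S(n)S(n−Ta)]/E[S²(n−Ta)]`; given `b`, `c = E[uv]/E[v²]` with
`u = x1(n) − b·x1(n−Ta)`, `v = x2(n) − b·x2(n−Ta)` (the stationarity
condition in `c`). The cost is biquadratic and can hold two valleys: a
shallow one near the raw projection `c0` (ignoring periodicity) and the
global one at (`c` = artifact ratio, `b ≈ 1`). The alternation
therefore runs from both the projection start and a periodicity start
(`b = 1`, `c` fitted on lag-differenced signals) and keeps the
lower-cost fixed point; a Nelder–Mead polish of the moment-form cost
cross-checks the result and overrides it (flagged) if it improves the
cost by more than 0.1 %. Expectations are batch frame means over the
lag-overlap region.

**Degeneracy.** On an artifact-free frame `x2` is almost perfectly
predictable at `Ta`, the cost is flat along `c`, and any `c` with
`b ≈ 1` near-minimizes it. This is detected when the unpredictable
power fraction `E[v²]/E[x2²]` falls below 0.05 and reported as
`converged = False`. The pipeline then carries the previous frame's
`β`; if none exists the reference is **zeroed** and the frame passes
through unfiltered. (Falling back to `N = x1` would hand the adaptive
filter a pulse-correlated reference and let it cancel the pulse
itself.)

**α, β, reference.** `α = E[x1·S]/E[S²]` (closed form, equal to the
1-D minimizer of the reference variance), `β = α·c/(α−1)` guarded
within 1e−6 of the `α = 1` pole, and `N(n) = x1 − β·x2`. A `|β| > 3`
estimate — beyond any plausible inter-wavelength amplitude ratio — is
treated like a pole (carry previous `β`).

**β error scaling.** The in-frame sample covariance between AC and the
band-limited MA is irreducible at fixed frame length and is amplified
into `β` by the MA/AC power ratio: the standard error scales as
`(c−a)·sqrt(P_MA / (P_AC·T·B_eff))`. Recovery of `β ≈ a` to ±0.05 is
therefore an SNR-dependent statement; the canonical battery uses MA SD
0.15 (≈ 27 % of the pulse SD), placing the estimate comfortably inside
that regime. At protocol-strength artifacts `β` is noisier, but there
the reference purity is insensitive to it — the MA term dominates
`N(n)` regardless.

## Entropy gate

`H = −Σ pᵢ·log2(pᵢ + ε)` with `ε = 1e−12`, where `pᵢ` are the power
fractions of 0.5 Hz sub-bands covering 0.5–5 Hz (nine sub-bands,
max H = log2 9 ≈ 3.17 bits), summed from the rectangular-window
periodogram of the whole frame. The aggregation is what keeps the fixed
threshold `HT = 2` meaningful for this generator: a pure tone or pulse
harmonic stays inside one sub-band even as the heart rate drifts across
fine periodogram bins (clean frames ≈ 1 bit; a tone scores ≈ 0, two
equal tones ≈ 1), while broadband artifact spreads over all nine
(≈ 3 bits). Entropy over the raw fine bins instead puts clean frames at
1.9 ± 0.25 — straddling the threshold — and a tapered-window PSD
(Welch/Hann) inflates even a pure tone to 1.25 bits. A frame is
strong-interference iff `H > HT` (strictly). The sub-band count is
frame-length independent, so partial frames are classified on the same
scale. `HT` calibrates to the PSD settings; both are exposed in config
rather than asserted universal.

## Adaptive filtering

Per frame, desired = conditioned `x2`, input = noise reference, FIR
weights updated by the LMS recursion with taps
`[N(n), …, N(n−N+1)]` (zeros before the frame start).

- **Reference standardization.** `N(n)` has arbitrary scale (it is a
  mixing-coefficient difference), while the behavior of a fixed
  learning-rate grid is governed by the loop gain `μ·N·P_ref`. The
  pipeline standardizes the reference to SD 0.1 so the soft/hard grids
  act at a known, small loop gain (≈ 1e−3): large enough for the
  dominant cancellation mode to converge within a fraction of a frame,
  small enough that weight jitter does not track — and partially
  cancel — the pulse itself. A zero reference stays zero.
- **Mode grids.** Soft: μ ∈ {3,4,5,6,7}×1e−4, N ∈ {25,30,35,40,45,50};
  hard: μ ∈ {8,…,15}×1e−4, N ∈ {51,60,70,80,90,100,110,120}. The grid
  search runs every frame, each candidate from zero weights with the
  same 3-pass budget (a fair within-frame comparison), minimizing the
  error-signal entropy; exact ties resolve to the smaller order, then
  the smaller rate. A diverged candidate scores +∞.
- **Steady-state emission.** The cleaned output is produced after
  weight convergence: the winning candidate's recursion is cycled over
  the buffered frame until its error entropy stops improving by 0.01
  bits (cap 50 passes), starting from the previous frame's final
  weights when the order repeats, else from the winner's own final
  weights. A single online pass at these learning rates either leaves a
  multi-second convergence transient in every frame or — if the
  reference is scaled up to converge faster — distorts the pulse; the
  per-sample update law is unchanged, only the number of passes over
  the (already buffered) frame differs. The per-frame batch remains
  implementable in real time with one frame of latency, which the grid
  search requires anyway.
- The startup parameter set quoted for streaming operation
  (μ = 5e−4, N = 132) is unused here: in frame-batch processing the
  first frame's entropy is available before filtering.

## Heart-rate metrics

- **Peaks**: local maxima with minimum separation `fs·60/180` and
  prominence ≥ 0.3 × the robust range (5th–95th percentile).
- **Windowed HR**: per 8-s window, `HR = 60 / mean(IBI)` over
  inter-beat intervals with both endpoints inside the window, after
  screening intervals the way HRV pipelines reject ectopic/artifact
  beats: outside [60/180, 60/40] s or > 30 % away from the window
  median (a missed beat doubles an interval; a spurious peak splits
  one). Fewer than two surviving intervals invalidates the window.
- **Alignment**: beat trains are smoothed with a 50 ms Gaussian kernel
  and cross-correlated over ±2 s; an argmax pinned at the boundary is
  flagged as clamped.
- **Agreement**: Pearson `R`, MAE, and Bland–Altman bias/SD/limits of
  agreement with the `est − ref` sign convention and the n−1 sample SD.
  Note that on a single protocol recording the true HR spans only a few
  bpm, so `R` is dominated by measurement noise there; MAE and LOA are
  the informative statistics at that scale.

## Numerical choices and degenerate inputs

- Expectations: arithmetic frame means; no recursive smoothing.
- Alternating fit: tolerance 1e−6 on `Δc`, ≤ 50 iterations per start.
- Pole guard 1e−6 on `|α − 1|`; `|β| ≤ 3` sanity bound.
- Constant signals: normalization raises a degenerate-range error;
  all-zero frames raise a zero-power error in the entropy.
- `μ = 0` freezes the LMS weights (diagnostic); negative rates raise.
- Failed frames are never dropped: every fallback is flagged in the
  per-frame diagnostics (`ta_fallback`, `cb_degenerate`,
  `beta_carried`, `beta_out_of_range`, `reference_zeroed`,
  `numeric_override`, `weights_carried`, `ta_refined`).
- CSV floats are written with 17 significant digits and re-read with
  round-trip parsing; fixed-seed runs are byte-identical.

## Known limitations

- The generator's pulse and artifact are idealized; in particular the
  artifact is *exactly* proportional across channels, the best case for
  the method. Real inter-channel MA correlation ≈ 0.9 would leave a
  correspondingly larger residual.
- `β` recovery to ±0.05 requires a moderate artifact-to-pulse ratio
  (see the scaling law); at strong contamination the reference remains
  artifact-dominated but `β` itself is imprecise.
- The entropy threshold `HT = 2` is calibrated to the 0.5 Hz sub-band
  PSD described above; other PSD settings require re-calibration.
- Processing is frame-batch (one frame latency); no online streaming
  runtime is shipped.
- SpO2 estimation is out of scope: the pipeline cleans the infrared
  channel's waveform and evaluates heart rate only.
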