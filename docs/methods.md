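# Methods

## Scope

`eegsync` implements a stimulus-level EEG neuroforecasting analysis:
per-stimulus inter-subject synchrony of alpha-band power, frontal alpha
asymmetry (FAA), and the two-level statistical ladder (group-level
correlations and popularity regressions; individual-level rank
correlations and stepwise model selection). Engagement is consumed as
an externally supplied probability in [0, 1] — the discriminant-function
classifier that produces such scores in commercial systems is
proprietary and is deliberately not reproduced. A synthetic-study
generator stands in for raw recordings, which are not publicly
deposited for studies of this kind.

## The synchrony estimator

Band power is computed in 500 ms Hann-tapered one-sided FFT
periodograms (density scaling, μV²/Hz), stepped by 250 ms; a band's
value is the mean over PSD bins whose centre lies inside the band,
edges inclusive. At 256 Hz the bin spacing is 2 Hz, so
delta/theta/alpha/beta/gamma cover bins {2}, {4,6}, {8,10,12},
{14..24}, {26..40} Hz. A 24 s stimulus yields
T = ⌊(24 − 0.5)/0.25⌋ + 1 = 95 frames.

For each frame t, each subject's response is the patch of alpha power
over C3/Cz/C4 spanning frames t−2..t+2. Numerical choices:

- **Window flattening.** The patch is flattened to a 15-vector and a
  single Pearson correlation taken per ordered subject pair — the only
  reading that yields one scalar per pair-frame.
- **Absolute value placement.** |r| is taken per pair-frame *before*
  any averaging; the ordered-pair denominator N(N−1) is retained (it
  equals the unordered mean for this symmetric kernel).
- **Scan step.** The synchrony scan advances one frame (250 ms) per
  step. An optional moving-average smoother exists for the reported
  time course only and never enters the scalar.
- **Edges.** Frames lacking a full ±2 neighbourhood are skipped, not
  padded: T_effective = T − 4. Frames overlapping masked samples, and
  patches with zero variance, are skipped and counted.
- **Correlation input.** Linear (not log) power is correlated, matching
  the estimator's definition; vendor pipelines may differ here, so
  absolute agreement with any particular commercial implementation is
  not claimed.
- **Reduction order.** Pair sums and the frame average accumulate
  left-to-right in a fixed order, so the scalar is exactly reproducible
  against a direct loop evaluation of the defining equation (asserted
  bit-for-bit on integer-valued fixtures in the test suite).

Under independence, the scalar converges to 100·E|r₁₅| ≈ 21.71 (closed
form 2/((m−2)·B(½,(m−2)/2)) at m = 15; a frozen 10⁶-pair Monte-Carlo
value is used in tests). Autocorrelated band-power series raise this
floor; measured synchrony for the default synthetic study sits at
~23–27.

## Preprocessing

- 50 Hz second-order IIR notch, −3 dB bandwidth 2 Hz; 0.1 Hz high-pass
  Butterworth of order 4. Neither order nor bandwidth are universal
  standards; order 4 is the conventional EEG choice. Both filters run
  forward–backward (zero net phase). The high-pass uses reflection
  padding of 3/f_c seconds (capped at the signal length): a 0.1 Hz
  corner settles over seconds, and scipy's default padding would leave
  >4% edge ripple at 10 Hz.
- The artifact gate is strict — |x| > 400 μV on any channel — and masks
  samples rather than modifying them ("removal" is read as exclusion;
  interpolation would fabricate data). The mask is dilated ±250 ms so
  no 500 ms band-power frame straddles an excursion. A recording more
  than half masked is flagged for quality review. Whether vendor
  pipelines drop whole epochs or samples is unpublished; masking with a
  guard band is this package's documented choice.

## Group-level inference

- **Outliers**: one pass; mean and SD from the full sample; |x − mean| >
  3 SD removed. Not iterated — a second extreme value exposed by the
  first removal stays (this matches how a single screening pass behaves
  on real streaming counts, where one mega-hit dominates). The
  Mahalanobis screen (χ²₀.₉₇₅ by default) only flags rows: the method
  prescribes no removal consequence, so none is invented.
- **Correlation gating**: Shapiro–Wilk at α = 0.05 per variable;
  Pearson iff both pass, else Kendall tau-b (tie-corrected — ratings
  and small samples have ties). Bonferroni: family α = 0.05 over m = 8
  group tests (two outcomes × four predictors) ⇒ 0.00625 per test,
  rounded to 0.006 in human-readable output; full precision in JSON.
- **Regression**: OLS; Shapiro on residuals and Breusch–Pagan at
  α = 0.05. If *either* fails, the outcome is natural-log transformed
  and refit (the source narrative only partially states which
  diagnostic triggered each transform; "either fails" is the
  implemented rule). On the log scale each coefficient is also reported
  as exp(b + σ̂²/2), the multiplicative effect on the conditional mean
  of a log-normal outcome; it reduces to exp(b) as σ̂² → 0. A
  numerically perfect fit (residuals at float-noise level) passes
  diagnostics by definition. Nested models are compared by partial F on
  residual sums of squares, with transform pinned to the base model's.

## Individual-level inference

Likeability correlations use Kendall tau-b over all pooled
(subject, stimulus) observations, family of m = 2 ⇒ 0.025. Genre
preference is binarized to pop-fan (favourite == pop); rank inputs must
be a permutation of the six offered genres.

Stepwise selection is bidirectional from the intercept-only model,
taking at each step the single add/drop with the largest AIC decrease
and stopping when none decreases (or when the fit is numerically
perfect, where AIC differences are float noise). The final AIC is the
minimum over the visited trace by construction, and matches an
exhaustive 2⁵-subset search in ≥ 95% of simulated datasets. Because the
source describes a "logistic" regression of a 1–5 outcome without a
binarization rule, both families are provided: `linear` (default) on
the raw score, and `logistic` on ratings binarized at ≥ 4, with
separation falling back to linear under a flag. Observations are pooled
over subjects (no random effects), matching a single pooled model; no
claim is made to replicate any particular published AIC value.

## The synthetic study

Defaults state the emulated world: 30 subjects × 24 stimuli × 24 s at
256 Hz, nine 10/20 channels, two artists splitting the stimuli 13/11
with four promotional singles each.

Channel model (μV), subject s, stimulus k, coupling w, valence v:

```
g_c · A · [ √w · A_k(t) sin(2π·10·t + φ_s) + √(1−w) · A_sk(t) sin(2π f_s t + ψ_sk) ]
  + pink(t) + ε(t)
```

- A_k: smooth stimulus-specific envelope (rectified < 2 Hz Gaussian
  noise, unit mean), identical across subjects; A_sk idiosyncratic;
  f_s ∈ [8, 12] Hz per subject.
- **Power-preserving mixing** (√w, √(1−w)): keeps total alpha power
  flat in w. With plain (w, 1−w) amplitude weights the alpha SNR — and
  with it the autocorrelation-driven baseline of |r| — varies
  non-monotonically in w, and measured synchrony at w = 0.3 falls
  *below* w = 0; the square-root weights make mean synchrony strictly
  increasing in w, which is the property the coupling dial exists to
  provide. The degenerate anchors (w = 0: no shared component; w = 1:
  identical recordings when noise and phase spread are silenced) are
  unaffected.
- Alpha gain g_c = exp(±(v + o_s)/2) on F4/F3 (1 elsewhere), with
  per-subject asymmetry offsets o_s ~ N(0, 0.2²), so expected FAA
  increases with valence. Default valence is a ±1 ramp reordered to be
  nearly uncorrelated with the default coupling ramp (0.15–0.75).
- Pink noise: 1/f-amplitude spectral shaping, RMS 10.3 μV — calibrated
  once so alpha-band SNR ≈ 1 at w = 0.5 (coupled and null regimes
  distinguishable but not trivially separable); broadband white noise
  1 μV.
- Artifacts: square pulses of 450–800 μV, 100–300 ms, Poisson at 0.5
  per minute — unambiguously beyond the 400 μV gate; injected indices
  are recorded in the ground truth.
- Outcomes: log(streams_early) = β₀ + β_synch·s(w) + β_single·single +
  N(0, 0.3²), streams in millions, with s(w) = 100·(r₀ + (1 − r₀)·w),
  r₀ = E|r₁₅| — the generative predictor on the synchrony scale, not a
  claim about the measured value. Late streams multiply early ones by a
  growth factor of 3 with independent log-normal noise. Ratings follow
  a cumulative-logit model centred on valence with fixed cutpoints
  (−1.5, −0.5, 0.5, 1.5); engagement is a logistic transform of a
  latent with a negative loading on ratings (base −2 gives mean scores
  near 0.12). Default β₀ = 0.5, β_synch = 0.02, β_single = 0.75 put
  simulated streams in the single-digit-millions range typical of
  album-release weeks.
- Determinism: every random draw comes from a seed-derived named
  substream; identical (config, seed) reproduce all arrays bit-exactly.

**What a green test establishes — and does not.** The generator
produces stationary envelopes, spatially independent noise, and no
volume conduction, eye or muscle artifact structure, or inter-subject
amplitude heterogeneity beyond the FAA offsets. Passing tests therefore
establish the *estimators and inference machinery* (recovery of known
generative parameters, correct gating, calibrated nulls), not that the
pipeline's absolute values match any commercial implementation on real
recordings. No distributional facts about the emulated study's raw EEG
are public; all generator constants are package choices, documented
here, not estimates of that study.

## Known limitations

- EEG interchange is long CSV only; EDF support would require an EDF
  library not available in the build environment.
- No ICA/regression ocular correction, no multitaper or wavelet PSD
  variants, no mixed-effects or ordinal-regression alternatives to the
  pooled individual-level models.
- The Bonferroni family sizes (8 and 2) are configuration defaults
  mirroring the emulated analysis plan, not derived quantities.
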