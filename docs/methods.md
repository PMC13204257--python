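# Methods

## Problem and decision unit

The pipeline screens carotid arteries for clinically actionable disease
(≥ 50 % stenosis or a non-atherosclerotic abnormality such as dissection)
from skin-surface acceleration recorded at the neck. The clinical decision is
made per carotid side, so the *patient-side* — one (patient, left/right)
pair — is the atom of everything: labels are per side, multiple 4 s segments
and two sensor positions per side are repeated measurements of the same unit,
and all data splitting, testing and aggregation respect that grouping.

## Signal preprocessing

Raw samples (clinically 60 s at 24 kHz) pass through, in order:

1. **Wrap-around repair** (integer input only): two's-complement
   reinterpretation within the stated bit width, then unwrapping of adjacent
   jumps larger than half the representable range by ± the full range. This
   is the standard treatment of fixed-width counter overflow; float input
   bypasses it.
2. **Decimation ×10** to 2.4 kHz with a zero-phase FIR anti-alias filter.
   The FIR choice (over the elliptic/Chebyshev IIR alternative) keeps the
   passband flat to < 0.1 % — a 5 Hz tone survives with amplitude error
   below 10⁻⁴ — and adds no phase distortion. Recordings generated directly
   at the analysis rate skip this stage.
3. **Band-pass 0.5–75 Hz**, Butterworth of total order 4 (two poles per band
   edge), −3 dB at both cutoffs by design, applied forward–backward
   (`sosfiltfilt`) for exactly zero phase. Zero-phase filtering squares the
   magnitude response; the −3 dB property is a statement about the
   single-pass design and is asserted as such.
4. **Z-score** per channel. This makes every downstream quantity invariant
   to positive amplitude scaling of the raw signal (sensor gain, coupling).
5. **Smoothing**: Savitzky–Golay (window 21 ms rounded to odd samples,
   polynomial order 3) followed by a 5 ms centered moving average, both with
   edge replication. These window choices are mild: deliberately small
   relative to the 5–60 Hz analysis band (the moving average attenuates
   60 Hz by ~14 % and 30 Hz by ~4 %), enough to suppress sample-level jitter
   without reshaping the band. All three values are configurable.
6. **Segmentation**: first 2 s discarded, 4 s windows with 2 s hop, only
   complete windows kept, so a 60 s recording yields
   floor((58 − 4)/2) + 1 = 28 segments of 9600 samples.

## Morse-wavelet scalograms

Each segment's continuous wavelet transform uses the analytic generalized
Morse wavelet, defined in the frequency domain as
Ψ(ω) = U(ω)·c·ω^β·exp(−ω^γ) with symmetry γ = 3 and time–bandwidth
P² = 60 (β = P²/γ = 20). The peak response sits at ω_peak = (β/γ)^(1/γ).
The implementation is a frequency-domain filter bank:

* **Frequency grid**: 12 voices per octave, f_k = 5·2^(k/12) Hz for
  k = 0 … 43 — 44 rows spanning 5–59.9 Hz, never leaving the analysis band.
* **Normalization**: every row's frequency response is peak-normalized to 1
  (the convention under which equal-amplitude tones produce equal-magnitude
  ridges). The normalizing constant is a convention only: all features are
  either energy ratios, normalized moments over the actual row frequencies,
  or computed on a max-scaled image, so a common rescaling of the bank leaves
  the entire feature vector unchanged (tested).
* **Boundary handling**: segments are reflected to double length before the
  FFT product and the central half retained, suppressing circular wrap.
* **Exact time decimation**: at 2.4 kHz the coefficient rows are heavily
  oversampled in time — the analytic filters vanish above ~120 Hz (the
  highest bin with response > 10⁻¹² is recorded at bank construction). The
  pipeline therefore samples the coefficients every 8th column (a 300 Hz
  scalogram frame rate) by truncating the product spectrum and taking a
  short inverse FFT. Because the retained spectrum contains every nonzero
  bin this is *exact*, not an approximation: the decimated rows equal every
  8th column of the full-rate transform to machine precision (asserted at
  run time against the recorded support, and tested). Full-rate computation
  (`time_decimate=1`) remains the reference path and is what the
  brute-force convolution oracle checks.

## Biomarkers

With S(f,t) = |W(f,t)|², E_tot = ΣS, and P(f) the frequency marginal:

| feature | definition | units |
|---|---|---|
| `hf_fraction_top50` | energy with f ≥ 32.5 Hz over E_tot | unitless [0,1] |
| `gini_sparsity` | Gini index of the sorted magnitudes | unitless [0,1) |
| `spectral_centroid_hz` | Σ f·P(f) | Hz |
| `sobel_edge_energy` | mean 3×3 Sobel gradient magnitude of the max-scaled image | normalized |
| `image_entropy` | −Σ p·ln p over cells, / ln N | unitless [0,1] |
| `spectral_spread_hz` | √Σ (f−C)²·P(f) | Hz |

The fractional band cut is f_cut = f_hi − q·(f_hi − f_lo); the upper 50 % of
5–60 Hz is 32.5–60 Hz. The extended screening set adds the q ∈ {0.3, 0.4}
ratios (to total and to the complementary lower band), the q = 0.5
ratio-to-lower, the 85 %/95 % cumulative-energy roll-offs, and upper/lower
entropy and Sobel ratios. The "proportion of the upper half-band" coincides
numerically with the q = 0.5 ratio-to-total for this band (the midpoint is
32.5 Hz), so it is not duplicated. Design choices where several readings were
possible: the core set uses the ratio-to-total variant (a "fraction"), the
full-band normalized entropy, Sobel on the raw (not log) max-scaled
magnitude, and the standard Gini sparsity index
G = 2Σ k·x₍ₖ₎/(N·Σx) − (N+1)/N. Centroid, spread and roll-offs use the
actual row frequencies in Hz, never row indices; discrete integration is
plain summation over grid cells, which cancels in every ratio and normalized
moment.

## Screening and modelling

* **Grouped CV**: stratified group k-fold is built greedily — groups are
  shuffled (seeded) and assigned class by class to the fold with the fewest
  groups of that class. A fixed holdout of ~15 % of groups (stratified, at
  least one group per class) precedes a 5-fold partition of the remainder.
  Leakage guards are hard assertions exercised in tests: no group on both
  sides of any split, standardization statistics from training rows only,
  threshold selection from training out-of-fold outputs only.
* **Univariate ranking**: each feature is used as a raw score and as its
  negation; held-out AUROC and AUPR are averaged over folds, the better
  orientation kept per metric, features ranked (rank 1 best, ties averaged),
  and the two ranks averaged. A classifier-based variant ranks
  single-feature logistic models over AUC, F1, PR-AUC and accuracy.
* **Consistency check**: feature values are first averaged per patient-side
  (matching the probability-averaging rule), then compared between classes
  with a two-sided Mann–Whitney U (U = pathological-over-non-pathological
  pairwise wins + half ties, the SciPy convention) under Benjamini–Hochberg
  FDR correction.
* **Classifier**: L2-regularized logistic regression fitted by damped Newton
  iteration on standardized features — class-weighted negative log-likelihood
  plus (λ/2)‖w‖² with the intercept unpenalized, converged to gradient
  ∞-norm ≤ 10⁻⁸. λ defaults to 1.0 on standardized features; class weights
  are inverse class frequency normalized to mean 1. Tree ensembles can be
  plugged in through the same protocol but the linear model is the core.
* **Aggregation and threshold**: patient-side probability is the arithmetic
  mean of the side's segment probabilities. The operating threshold is the
  lowest candidate (midpoints between adjacent sorted unique probabilities
  plus boundary sentinels) achieving out-of-fold training sensitivity
  ≥ 0.90, ties resolved toward maximum specificity and then toward the lower
  threshold; it is applied unchanged to the held-out test set.
* **Metrics**: AUROC by the rank/trapezoid convention (ties count ½, equal to
  the O(n²) pairwise statistic), AUPR by step-wise precision–recall
  integration (no linear interpolation between points); thresholded
  sensitivity/specificity/precision/F1/accuracy with confusion matrices in
  counts and percentages, at both segment and patient-side resolution.

## Attribution

For the linear model with the independent-feature (interventional)
convention, the Shapley value of feature i is exactly wᵢ·(xᵢ − μᵢ) on the
log-odds scale; after standardization the background is the zero vector, so
φᵢ = wᵢ·x_std,ᵢ and the base value is the intercept. Additivity
(base + Σφ = predicted log-odds) holds to machine precision for every row —
this exactness is why attributions are reported on the log-odds rather than
the probability scale (the sigmoid maps them monotonically). Global
importance orders features by mean |φ| with a sign-consistency summary.

## Synthetic cohorts

The generator emulates what the clinical recordings are described to contain,
not their absolute physical magnitudes:

* **Per patient**: heart rate ~ N(70, 10) bpm (clipped 40–140), pulse
  oscillation frequency ~ U(8, 15) Hz, second-harmonic amplitude ~ U(0, 1)
  and pulse ring-down time 0.66–1.5 × 60 ms — real carotid pulses are
  non-sinusoidal and vary in waveform across subjects, and this morphology
  heterogeneity is what keeps simple energy-location features (centroid)
  from being implausibly clean discriminators.
* **Per side**: severity in [0, 1]; pathological iff severity ≥ 0.5 (the
  synthetic analogue of the ≥ 50 % stenosis cut). Pathological sides draw
  severity ~ U(0.5, 1), others ~ U(0, 0.5). Each side also draws a bruit
  phenotype: 75 % stenosis-like (turbulence band shifted down by U(0, 6) Hz
  from the nominal 20–40 Hz) and 25 % dissection-like (shifted up, broader
  reach toward 25–46 Hz) — dissections are the minority phenotype
  clinically.
* **Per recording**: beat times with 4 % RR jitter and ±10 % amplitude
  jitter; turbulence bursts of steeply band-limited Gaussian noise
  (8th-order Butterworth, so the burst is genuinely confined to its band)
  gated by a Hann window over the systolic interval, with amplitude
  severity² × gain (convex dose-response: lower-stenosis sides show
  essentially no mid-band elevation, and moderate stenoses much less than
  near-occlusions); white sensor noise with SD 0.08 × U(0.5, 1.5)
  (coupling/skin variation between placements); sub-0.5 Hz drift; position 2
  applies a log-normal gain factor (SD 0.15).
* **Reproducibility**: one master seed; every random draw comes from a
  substream keyed by content (patient, side, position, component) via a
  stable hash, so cohorts are bit-identical regardless of generation order.
* **Fast mode** generates directly at 2.4 kHz (flagged in the manifest) so
  tests need not pay for the ×10 decimation of 24 kHz audio; the raw-rate
  path is exercised separately.

What the generator does *not* emulate — and hence what passing tests do not
show about clinical data: motion/swallowing artifacts, contralateral
hemodynamic coupling, vessel-wall mechanics or any calibrated physical
amplitude scale, demographic covariates, and real label noise from imaging.
Synthetic discrimination numbers characterize the pipeline, not the device.

## Problem sizes used by the test suite

The end-to-end discrimination check runs ten cohorts of 60 patients
(2 sides × 2 positions, 60 s at 2.4 kHz fast mode → 6720 segments per
cohort); null-calibration uses 100 label permutations of a 20-patient cohort;
the severity sweep uses 11 severity values × 3 seeds × 2 positions. These
sizes were chosen so the whole suite runs on a single CPU in minutes while
keeping Monte-Carlo noise well inside the asserted margins.

## Known limitations

* The severity → turbulence dose-response (convex, exponent 2) is a modelling
  choice; only its monotonicity is treated as load-bearing.
* The logistic model's weight signs on strongly collinear biomarkers are
  only meaningful jointly; the univariate ranking and the attribution
  summaries are the interpretable outputs.
* The Mann–Whitney p-values use the tie-corrected normal approximation for
  larger samples (SciPy's default switching rule); exact enumeration applies
  only to small untied samples.
* `wraparound_to_float` assumes at most one wrap event between adjacent
  samples, which holds whenever the sampling rate is fast relative to signal
  slew.
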