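# Methods

This note documents the models, estimators and numerical choices behind
`natsynth_fus`, and what the synthetic-data generator does and does not
emulate.

## The measurement model

A passive-listening experiment presents a set of natural sounds and, for
each, a synthetic counterpart matched on time-averaged cochlear and
modulation statistics. Trials are 20 s (7 s silent baseline, 10 s sound,
3 s post-stimulus) sampled at 1 Hz; each sound is repeated (4 repetitions
by default) while coronal slices are imaged in separate sessions. A
voxel's response to a sound is summarized by its baseline-normalized
signal averaged 3–11 s after stimulus onset. All dissimilarity statistics
operate on the resulting voxel × sound matrices, held separately per
repetition split.

The data model behind every estimator is `measurement = signal + noise`
with noise zero-mean and independent across repetitions and slices. The
corrected statistics (below) are exact under that assumption; motion is
the deliberate violation (it correlates with the sound being played), and
the CCA scrub exists to restore it.

## Synthetic data (`synthgen`)

The generator plants everything downstream stages must recover:

* **Latent structure.** `K = 8` component response profiles over sounds
  (standard normal, plus a +1.5 preference of component *k* for the *k*-th
  sound category so that category profiles and feature attributions have
  signal). Synthetic sounds share their natural counterpart's latent
  profile exactly — divergence enters only through the planted gap. Voxel
  weights are log-normal (shape 0.7), median-subtracted, spatially
  smoothed (Gaussian, 0.4 mm), giving the positive-excess-kurtosis
  distributions the histogram-entropy decomposition needs.
* **Hemodynamics.** The evoked timecourse is a gamma CDF build-up
  (shape 3, scale 0.7 s; ~2 s rise) minus its echo at stimulus offset —
  i.e. a gamma-variate kernel convolved with the 10 s boxcar — normalized
  to unit mean over the 3–11 s window so planted response amplitudes are
  in window-average units. The response peaks inside the analysis window.
* **Noise.** White repetition noise per voxel/sample; slice-common noise
  (shared by all voxels of a slice, independent across slices, 0.01
  fractional units); and motion (below). `snr` is defined as the ratio of
  window-averaged evoked variance (across sounds) to window-averaged
  single-repetition noise variance; `snr = 1` (the default) puts a single
  repetition's tuning-curve measurement at parity with the signal. With
  the default window (8 samples) this implies a per-sample repetition
  noise s.d. of `signal_sd · √8 ≈ 0.14` around a 5% signal.
* **Motion.** Per (slice, trial): a half-normal amplitude whose scale
  depends on the sound's category (natural vocalizations 0.08, natural
  speech 0.05, otherwise 0.02 fractional units) times a smooth unit-RMS
  trace confined to the stimulus period, loaded onto every voxel of the
  slice through a spatially striped loading pattern (period 1 mm) that is
  nonzero both inside and outside cortex. Amplitudes differing by category
  *of the natural sound only* create the sound-correlated confound.
* **Gap.** In "human" mode each cortical voxel's natural-sound responses
  are shifted upward by `gap_max` (default 1) times the voxel's response
  s.d., scaled linearly from 0 at the distance-to-PAC minimum to `gap_max`
  at the maximum; in "ferret" mode the gap is identically zero.
* **Geometry.** Six slices 0.6 mm apart; per slice a 16 × 4 cortical
  sheet at 0.25 mm pitch plus 20 out-of-cortex voxels below it; the PAC
  center is the cortical centroid, distances are Euclidean.

Raw data are emitted as power-Doppler-like arbitrary units
(`baseline · (1 + fractional)`, baseline ~ U(80, 120)) so the
percent-signal-change stage has real work to do. All draws flow through
one seeded `numpy.random.Generator`.

Separate small generators provide: ultrafast Doppler frame stacks (rank-
limited high-energy tissue motion + a diffuse-plus-vessels blood map +
white noise, with the true blood power stored) for the clutter filter; a
pure-tone dataset with a monotone tonotopic gradient for best-frequency
mapping; and face-video frames whose frame-to-frame jitter follows a
planted per-trial motion schedule.

**What the generator does not emulate** — and hence what green tests do
not certify about real recordings: vascular anatomy and pulsatility,
registration error and slow drifts, non-Gaussian or temporally correlated
sensor noise, hemodynamic nonlinearity and adaptation across the 10 s
stimulus, voxel-size-dependent partial-volume effects, and any dependence
of the evoked *timecourse shape* on the sound. Tests establish that the
estimators recover what was planted under the stated noise model, not
that the model exhausts real data.

### Scale of the study conditions

Desk-scale sizes are used throughout: 40 natural/synthetic pairs in four
categories, 4 repetitions, 6 slices, 384 cortical + 120 out-of-cortex
voxels. Real recordings have two orders of magnitude more voxels; two
consequences of the smaller scale are documented below (in-sample CCA
leakage; DSS weight-estimation noise).

## Preprocessing

* Window membership is half-open: a sample belongs to `[start, end)`
  seconds post-onset judged at its center; at 1 Hz this makes the 3–11 s
  window exactly 8 samples and avoids double counting.
* Percent signal change subtracts each trial's mean baseline and divides
  by the voxel's session-mean baseline. Note the subtraction injects the
  baseline estimate's noise (`σ²/n_baseline`) as a common-mode term that
  does not average down over the analysis window;
  `GroundTruth.timeavg_noise_var` accounts for it.
* The clutter filter computes the SVD of the (time × pixels) frame stack
  and removes the leading `n_discard` components (default 55) before
  summing squared magnitudes per pixel. Total output power is
  non-increasing in `n_discard`.
* Best frequency is the argmax across tone responses averaged 3–5 s
  post-onset; ties break toward the lower frequency and are flagged.

## Denoising part I: CCA scrub (`scrub_cca`)

For each slice (each slice is an independent session): subtract each
sound's across-repetition mean timecourse from every trial (sound-locked
activity is reliable across repetitions; motion is not), concatenate the
residual trials, and run CCA between in-cortex and out-of-cortex residual
matrices. Covariances are ridge-regularized (shrinkage 10⁻³ of the mean
eigenvalue) because voxel counts can exceed timepoints. The noise basis is
the top-k (default 20) canonical variates **from the out-of-cortex side**,
which by construction cannot contain cortical stimulus responses. Each
voxel's *full* timecourse then has its least-squares projection onto the
basis subtracted — applying to full data, not residuals, is what removes
the noise component that is correlated with sound identity.

Two properties worth knowing:

* **All-repetition averages are exactly invariant.** Residual timecourses
  sum to zero across the repetitions of each sound, so any linear
  functional that averages all repetitions (e.g. the full-average response
  matrix, or a natural-minus-synthetic map computed from it) is unchanged
  by the removal — exactly, not approximately. The scrub's benefit shows
  in single-split responses, split-half reliability, and any trial-level
  analysis; tests of striping attenuation therefore measure single-split
  difference maps along the planted motion-loading direction.
* **In-sample leakage at desk scale.** The basis is fit on, and removed
  from, the same data; each voxel's projection coefficients mix all
  trials, so the cleaned odd split inherits a trace of even-split noise.
  With hundreds of voxels and thousands of timepoints this is measurable:
  it inflates apparent split-half reliability in proportion to motion
  strength and, under a strong motion confound, biases the DSS
  cross-validation toward too many components. At realistic data sizes
  the effect is negligible. This is why the generator's default motion is
  moderate while the scrub-efficacy tests plant a deliberately prominent
  confound (vocalization scale 0.4) — the scenario that stage exists for.

## Denoising part II: DSS (`dss`)

Each (repetition, slice) matrix of concatenated in-cortex sound
timecourses is whitened individually (SVD whitening; dimensions below
10⁻⁶ of the top singular value dropped; covariance is identity on the
retained subspace). Whitened matrices are averaged across repetitions
(reinforcing repeatable structure), concatenated across slices along the
voxel axis (slice noise is independent, so cross-slice consistency marks
stimulus-driven activity), and the top-N left singular vectors of the
concatenation are the reliable components `R`. Denoising projects data
onto their span, `R R⁺ D`.

Component count is chosen by cross-validation: sound *pairs* are split
75/25, stratified by category, with a natural sound and its synthetic
always on the same side; `R` is fit on train sounds, voxel weights
`W = R⁺ D_train` computed, and held-out responses denoised as
`(D_test W⁺) W` — nothing is refit on test data (the weights fully
determine the test projection). Reported per N: median split-half
correlation of window-averaged test responses before denoising, after
denoising one split, after denoising both, and the upper bound
`√(split-half reliability)`. An optional repeated-cross-validation mode
averages the summaries over several independent splits; the curve on a
25% test set is otherwise noisy.

At the default SNR of 1 the cross-validation curve peaks at the planted
component count (median argmax 8 across seeds; individual seeds can land
on the flat tail above it), and denoising both splits pushes split-half
correlations near 1. Denoising one split tracks the √reliability bound
but sits ~0.05–0.08 below it: with oracle (planted) weights the gap
nearly closes, so the shortfall is estimation noise in `W` at this SNR
and repetition count, not a property of the projection. It does not
shrink with more voxels.

## Noise-corrected NSE (`nse`)

`NSE = μ((x−y)²) / (μ(x²) + μ(y²) − 2 μ(x) μ(y))`. Expanding the
numerator isolates powers, means and the cross-product; means and
cross-products are unbiased under zero-mean noise, powers are corrected by
subtracting half the split residual power
(`μ̂(x²) = ½μ(x₁²) + ½μ(x₂²) − ½μ((x₁−x₂)²)`). Choices:

* The cross term uses the average of `μ(xᵢ ∘ yⱼ)` over all four split
  pairings — each term is unbiased (independent noises), and the
  symmetric average has the lowest variance.
* Negative corrected powers are retained in the algebra (clipping would
  bias medians); voxels with non-positive corrected denominator are
  excluded from the validity mask, as are voxels whose test–retest NSE
  (both conditions pooled, split 1 vs split 2) exceeds 0.4. Values are
  still reported for excluded voxels.
* A `noise_from="x"` variant estimates the noise power from the repeated
  condition only, for designs where only one condition is repeated.
* The corrected signal variance is `(var(r₁+r₂) − var(r₁−r₂))/4`, which
  equals `var(s)` exactly under the additive model.

The spatial correlation profile correlates, across sounds, every voxel of
split A with every voxel of split B, symmetrizes, and bins by pair
distance (the 0 mm bin is test–retest reliability). τ₇₅ subtracts the
minimum correlation across distances (removing any global shared floor),
then solves `f(τ₇₅) = 0.25 · f(0)` by linear interpolation at the first
crossing. A profile that never crosses yields NaN.

## Component decomposition (`components`)

`D (voxels × features)` is reduced by SVD; the whitened voxel weights
`U_K √V` (unit variance, uncorrelated — the space in which an orthogonal
rotation spans all candidate unmixings) are rotated to minimize the summed
differential entropy of the K weight columns, estimated by histogram: 100
equal-width bins over the 1st–99th percentile range, add-one smoothing,
plus the log bin-width term that keeps the estimate scale-aware.
Optimization is Jacobi-style sweeps over column pairs; each pair's angle
is found by a 17-point coarse grid on `[−π/4, π/4)` (the objective is
π/2-periodic and can be multimodal) refined by golden-section search, with
10 seeded random restarts and the best objective kept. Components are
sign-flipped so weight skewness is positive, weights normalized to unit
RMS (magnitude moves to the profiles), and per-component variance shares
sum to 1. If no weight column shows excess kurtosis beyond five standard
errors of a Gaussian's (floored at 0.5), the result is flagged
unidentifiable — with Gaussian weights the entropy objective is flat and
the rotation meaningless.

Cross-species prediction: each target component profile is regressed on
all source profiles with 9-fold ridge regression; folds contain whole
natural/synthetic pairs, the penalty is chosen per outer fold by nested
9-fold cross-validation over 201 log₂-spaced values from 2⁻¹⁰⁰ to 2¹⁰⁰
(edge selections logged), and predictions are assembled out-of-fold.
Accuracy is the NSE computed separately on synthetic-sound responses
(frequency/modulation tuning) and on natural-minus-synthetic differences
(higher-order sensitivity); explained variance is the *signed* square of
`1 − NSE` (an anti-prediction stays negative; unsigned squaring would bias
bootstrap distributions). Bootstrap intervals resample sound pairs with a
seeded generator (1000 draws by default) and are bit-reproducible. When
two independent measurements of the target exist, the NSE is
noise-corrected unless the target's own test–retest NSE exceeds 0.4 (the
correction itself becomes unreliable), and component total variance is
corrected via the `(var(r₁+r₂) − var(r₁−r₂))/4` estimator.

## Acoustic features (`acoustic_features`)

Cochleagrams: 40 4th-order gammatone channels, log-spaced 100 Hz to
0.4 × sample rate, envelope by analytic signal, power-law compression
(exponent 0.3), envelopes resampled to 400 Hz; waveforms are RMS-
normalized first so features are level-invariant. Modulation filters are
log-Gaussian transfer functions (σ = 0.5 octave) applied in the 2D Fourier
domain of the cochleagram: nine temporal rates (0.5–128 Hz, octave
spaced), six spectral scales (0.25–8 cyc/oct), and their 54 joint
products; joint filters are applied without orientation separation (both
drift directions pooled), a simplification adequate for energy
measurement. Modulation strength is the s.d. over time of each channel of
the filtered cochleagram, averaged over channels; rates above the envelope
Nyquist or with fewer than two periods in the signal are NaN. Cochlear
energy is the time-averaged cochleagram.

Attribution uses the maximum signed correlation across a feature group's
columns as the statistic; the null permutes the sound correspondence
(seeded), and the two-sided p doubles the smaller tail overlap, floored at
`2/(n_perm+1)`. Under the null the p-values are uniform to the test's
resolution, so the type-I error is at the nominal level.

## Spatial statistics (`spatial_stats`)

* Surface projection: mean over each vertical column of masked voxels.
* Annular profiles: voxels binned by distance to the PAC centroid
  (Euclidean; the centroid stands in for the tonotopically defined
  center, which `preprocess.best_frequency_map` can supply); median NSE
  per bin; slope by unweighted OLS on bin medians vs bin centers over
  populated bins, using absolute distances. With coarse bins the
  within-bin median distance deviates from the bin center and biases the
  slope slightly toward zero; tests use fine bins where exact recovery is
  asserted.
* Species comparison: each individual slope is tested against the
  distribution of comparator slopes with an exact two-sided binomial sign
  test (ties dropped and logged); a slope below all 12 comparators gives
  p = 2 · 0.5¹² ≈ 4.9 × 10⁻⁴.
* Model comparison: per bootstrap draw the sound axis is resampled with
  replacement, the per-voxel corrected NSE recomputed from the response
  matrices (never from cached NSEs), and the across-voxel median taken;
  the two-sided p doubles the smaller overlap fraction (`≥`/`≤`, so
  identical models give p = 1), floored at 2/n_boot.
* Category NSE: the numerator (corrected residual power) is restricted to
  a category's sounds while the denominator is computed from all sounds,
  so normalization cannot erase category differences; the category
  values, weighted by category size, exactly recompose the all-sound
  statistic. Per-sound values feed Wilcoxon rank-sum comparisons across
  categories.
* Difference maps divide the mean natural-minus-synthetic difference by
  each voxel's response s.d. across all sounds (scale-free, comparable
  across subjects); zero-s.d. voxels are NaN.
* Motion index: per-frame sum of absolute frame-to-frame deviations over
  the ROI, converted to evoked units exactly like the imaging signal
  (trial baseline removed, session-mean baseline divided), normalized per
  session by the s.d. across sounds (canceling camera gain and angle),
  then averaged across sessions. A perfectly still camera yields zeros
  rather than a division error.

## Degenerate inputs and tie-breaks

Constant equal-mean vectors make the NSE denominator zero → NaN, flagged.
Sounds with a single repetition are excluded from residual fitting with a
warning. Requested component counts above the data rank are truncated with
a warning. Empty distance bins are dropped; profiles that never cross the
τ₇₅ criterion return NaN. Best-frequency ties break toward the lower
frequency and are counted. Ridge-penalty selections at the grid edge are
logged.

## Known limitations

* The exact CCA variant and removal algebra of the original denoising
  procedure are not fully specified by its public description; this
  implementation is a faithful reconstruction (residual-fit, out-side
  variates, full-data removal) but numerical equality with any particular
  dataset's published outputs is not expected.
* Held-out DSS denoising sits below the √reliability bound at SNR ≈ 1 by
  the weight-estimation margin described above.
* The histogram-entropy decomposition needs many voxels; below a few
  thousand samples the entropy estimate is noisy and recovery degrades.
* Modulation filters are unoriented; studies of direction-selective
  (upward/downward-sweep) energy need the oriented quadrant separation.
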