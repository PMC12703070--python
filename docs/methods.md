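# Methods

This note documents the models, conventions and numerical choices behind
`neurotyp`, and what the synthetic-data studies do and do not establish.

## Typicality of evoked activity

Inputs are per-subject K × T matrices of signal time courses (ICA
components or atlas ROIs) sampled at TR = 2.5 s during three concatenated
video segments (600 s, 485 s, 700 s → 240, 194 and 280 volumes; durations
are converted to volumes by exact division when divisible by TR, otherwise
floored, with cumulative 0-based half-open boundaries).

The full concatenated series is band-pass filtered **before** any segment
is sliced out (filtering is a preprocessing step; windowing is an analysis
step). The filter is a second-order Butterworth band-pass, 0.009–0.1 Hz,
applied forward–backward (`sosfiltfilt`) with reflective edge padding —
the conventional zero-phase choice for fMRI. Only the filter family and
band are externally fixed; order and phase handling are package choices
and are recorded in the run log. Series containing NaN are rejected rather
than imputed: the statistic is a plain correlation and silent imputation
would bias it.

The typical time series is the per-signal, per-volume subject mean of the
filtered series, without per-subject standardisation (plain averaging; a
per-signal z-scoring flag exists for sensitivity analyses). The
typicality index is the arithmetic mean of the K subject-vs-typical
Pearson correlations — deliberately *not* Fisher-z averaged, as the index
is defined as a mean of correlation coefficients; z-averaging is available
behind a flag. Degenerate (constant) signals raise errors instead of
propagating NaN.

### Outlier handling

Subjects are flagged when their index lies more than `multiplier` (default
1.5) interquartile ranges outside the quartiles. Quartiles use linear
interpolation between order statistics (the "type 7" rule, numpy's
default); the convention matters near fences and is therefore explicit and
configurable. By default exactly one remove-and-recompute pass is made:
indices on all subjects → flag → drop → recompute typical series and
indices on the reduced cohort. `outlier_passes` can iterate the loop; `0`
disables removal.

Per-segment analyses reuse the all-stimuli outlier set by default, keeping
n constant across the stimulus columns of reported tables;
`redetect_outliers_per_segment` reruns the fences per window and restricts
to subjects surviving everywhere.

Note a structural property of Tukey fences relevant to simulation studies:
for ~40 approximately Gaussian indices the probability that *no* natural
value falls outside the 1.5-IQR fences is only ~0.75–0.85, independent of
scale. Planted gross outliers are recalled essentially always, but
exact-set identification fails in a nontrivial fraction of replicates
because one genuine subject sits marginally outside a fence.

### Include-self vs leave-one-out

The default includes the assessed subject in the typical series (the
group-template convention). This biases indices upward — each subject
correlates partly with their own contribution, by roughly 1/n plus a
noise-dependent term — and the leave-one-out switch removes that bias.
Synthetic studies here show the bias is always positive at cohort level
while the downstream association estimates move by < 0.01 on average at
n = 80, so the default is reported with leave-one-out as a sensitivity
switch.

## Personality PCA

The 12 trait scores are standardised per trait before PCA (the two
inventories use very different scales), i.e. PCA is an eigendecomposition
of the trait correlation matrix; covariance-matrix PCA is available via
`standardize=False`. Component count defaults to a fixed k = 2 — scree
inspection is a human judgement, not automated — with a
cumulative-threshold rule as the alternative.

Component signs are fixed deterministically so that each loading column
sums to a positive value (falling back to making the largest-|loading|
entry positive when the sum is numerically zero). The more common
argmax-|loading| rule is unstable when two traits compete for the largest
loading — exactly the situation here, where Neuroticism (negative) and
Cooperativeness (positive) both load heavily on the first component — and
a sign that flips across resamples would scramble the sign of every
downstream correlation. The column-sum rule encodes the orientation an
analyst would choose by inspecting the loading pattern and is stable under
resampling.

## Association statistics

* **Spearman**: Pearson correlation of mid-ranks (average ranks on ties);
  two-sided p from t = ρ√((n−2)/(1−ρ²)) with n−2 df. For n ≤ 9 the exact
  permutation distribution is enumerated instead. At the cohort sizes used
  here (n ≈ 80) the t approximation is accurate and fast.
* **Partial Spearman**: all variables mid-rank transformed; x- and y-ranks
  residualised on the covariate ranks (with intercept) by least squares;
  ρ is the Pearson correlation of residuals, p uses n − 2 − k df. This is
  the standard rank-residualisation estimator of a partial rank
  correlation.
* **Anderson–Darling normality** (composite null, mean and SD estimated):
  the order-statistic formula with the small-sample modification
  A*² = A²(1 + 0.75/n + 2.25/n²) and the published piecewise
  approximation for p. The normal CDF is clipped away from {0, 1} so
  heavily discrete inputs (e.g. a binary sex code) yield a finite, huge A²
  and a rejection rather than log(0). Calibration simulations put the 5%
  rejection rate within (3.5%, 6.5%) under the null at n = 100.
* **BH-FDR**: the step-up definition q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j, capped at
  1, mapped back to input order. Family boundaries are explicit: the
  primary block (PCs × analysis windows, 8 tests), the per-trait block
  (12 × 4 = 48), the per-signal block (12 × K), and the FC block (12) are
  each one family by default and are tagged in the output tables. The
  exact pooling used in any given report is configurable because
  reasonable analysts pool these blocks differently.
* **CCA**: canonical correlations and weights from QR orthogonalisation of
  the centered blocks and an SVD of Q_xᵀQ_y (numerically a whitened
  cross-covariance decomposition). Significance uses sequential Wilks
  Λ_d = Π₍ᵢ≥d₎(1 − rᵢ²) with Rao's F approximation: with p' = p − d + 1,
  q' = q − d + 1, df1 = p'q', s = √((p'²q'² − 4)/(p'² + q'² − 5)) (s = 1
  in the degenerate cases), w = n − 1 − (p' + q' + 1)/2 and
  df2 = ws − p'q'/2 + 1. For 12 and 39 variables at n = 79 the first
  dimension has df = (468, 364). df2 is reported rounded but used as a
  real number in the p computation. Bartlett's χ² is not implemented; the
  F form is the default because it is the one whose df structure the
  reported analyses carry. Inputs whose centered blocks are rank deficient
  — in particular more features than observations, as with 90 ROIs and 81
  subjects — raise a `RankDeficiencyError`; pipeline runners catch it and
  place the message in the report instead of results. No regularised or
  permutation-based CCA is offered.
* Sex is coded 0/1 and handled by the same rank machinery (point-biserial
  on ranks). The age/sex confound check uses uncorrected Spearman
  correlations, mirroring how such checks gate, rather than belong to,
  the corrected families.

## FC typicality

Each subject's K × K functional-connectivity matrix is the Pearson
correlation of their (filtered, full concatenated) signal time courses.
The subject's FC typicality is the Pearson correlation between the
vectorised upper triangle (diagonal excluded — constant 1s) and the
element-wise mean triangle over included subjects, with the same IQR
machinery; K ≥ 3 is required since K = 2 leaves a single triangle entry.
Raw correlations are used in both the mean and similarity steps; a
Fisher-z flag exists. Because FC typicality is age-related, trait
associations for it use age-partialled Spearman correlations and raise if
age is missing.

## Synthetic cohorts

The generator produces the minimal structure the statistic is sensitive
to, nothing more:

* **Shared signals** g_k(t): white Gaussian noise given an ideal
  (brick-wall) band filter in the frequency domain, supported on
  0.012–0.09 Hz — safely inside the analysis band so the Butterworth
  filter passes them essentially unchanged — then standardised per
  signal. No hemodynamic model, scanner-noise spectrum or volumetric
  structure is simulated.
* **Subject series**: x₍ₛ,ₖ₎(t) = aₛ·g_k(t) + √(1 − aₛ²)·ε with white
  unit-variance idiosyncratic noise, so aₛ is the pre-filter population
  correlation with the shared signal. Coupling acts uniformly across
  components by default; `per_component_coupling_sd` adds heterogeneity.
* **Couplings**: aₛ = clip(a₀ + β·f₁ₛ + σ_c·ηₛ, 0, 1), with f₁ the first
  latent trait factor. The subject-level noise term σ_c·η is essential:
  without it the index is a nearly noiseless monotone function of f₁ and
  the population Spearman between typicality and the factor is ≈ 1
  regardless of β. Defaults a₀ = 0.5, β = 0.05, σ_c = 0.15 put that
  population Spearman at ≈ 0.30 — the moderate effect size the analysis
  is designed to detect — with negligible boundary clipping. Planted
  outliers are pure-noise subjects (aₛ = 0). An `age_effect` knob couples
  standardised age into aₛ to exercise the partial-correlation path; age
  (uniform integers 18–46) and sex (balanced binary) are otherwise
  independent of everything.
* **Traits**: 12 scores from a two-factor model, scoreₛⱼ = Lⱼ·fₛ + noise
  (SD 0.45). Factor 1 loads negatively on N and HA and positively on Co,
  A, SD, E; factor 2 is an openness-like mixture. The two loading columns
  are chosen near-orthogonal so that correlation-matrix PCA recovers the
  planted factors cleanly (corr(PC1, f₁) ≈ 0.95 at n ≈ 80). The implied
  trait intercorrelations (r(N,HA) ≈ 0.75, r(A,Co) ≈ 0.74,
  r(E,HA) ≈ −0.65) match published adult samples; a consequence of the
  clean two-factor structure is that the first two PCs explain ~72% of
  trait variance, more than the ~55% typical of real inventories whose
  residual dimensions are not white noise.

### What the simulations establish — and not

Passing the synthetic studies shows the pipeline is internally coherent:
the statistic estimates what the generative model plants, FDR is
calibrated under the null, the include-self bias behaves as documented,
and outliers of the planted kind are recalled. It does **not** show
anything about real BOLD data, whose noise is autocorrelated and
non-stationary, whose "shared signal" varies by region and stimulus, and
whose trait–brain couplings need not be linear in a latent factor.

## Problem sizes used in checks

The automated checks run the pipeline at the study's scale where the
quantity depends on it (n = 80, K = 39, T = 714 for effect recovery and
the leave-one-out switch; n = 79 for the CCA df structure), and at reduced
sizes where it does not (null calibration uses K = 20, T = 238 — the
calibration of rank tests and BH-FDR does not depend on the series
dimensions; include-self bias direction uses many small cohorts). The
population oracle for the planted effect simulates 50 000 subjects against
the infinite-cohort typical series (which is proportional to the shared
signal itself). The pipeline's mean estimate sits slightly below the
population typicality–factor value because PC1 is a noisy estimate of the
factor (attenuation ≈ corr(PC1, f₁)); the recovery check compares the two
within ±0.05.

## Known limitations

* No NIfTI/CIFTI ingestion, ICA estimation, or ROI extraction — inputs
  are already-extracted time-series tables.
* No inter-subject correlation matrices, dynamic FC, graph measures,
  permutation CCA, factor rotation, or item-level inventory scoring.
* The exact-set identification rate of the IQR procedure on near-Gaussian
  index distributions is bounded by the fences' natural false-positive
  rate (see above); this is a property of the rule, not of its
  implementation.
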