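# Methods

This note documents the models and procedures implemented in `eventshift`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## The ordered-event HMM

A brain region's response to a structured naturalistic stimulus is modeled
as a traversal of K discrete events, each with a fixed spatial activity
pattern m_k (z-scored across features). The latent state starts in event 0,
may only stay or advance by one event per TR, and is conditioned on
occupying event K−1 at the final timepoint, so every event is visited.
Observations x_t (a feature vector per TR, z-scored across features before
comparison) are emitted as isotropic Gaussians N(m_k, σ²I) with a single
variance σ² shared across events and viewings.

Transition probabilities use a uniform advance probability p = K/T (the
expected dwell time is then T/K) and are not fitted. Every state, including
the last, keeps the same stay probability 1−p; combined with the end-state
conditioning this makes every admissible segmentation carry the same
transition weight, so the posterior over segmentations is purely
emission-driven. Two useful consequences: the posterior is exactly the
likelihood-weighted average over all C(T−1, K−1) monotone segmentations
(which the test suite verifies against brute-force enumeration), and it is
time-reversal symmetric (reversing the data and the pattern order reverses
the posterior).

Posteriors are computed by the forward–backward algorithm in log space.
**Joint fitting**: for multiple viewings of the same stimulus the E-step
runs forward–backward per viewing, and the M-step pools the posteriors:

* event patterns = posterior-weighted average of the (column-z-scored) data
  summed over viewings, re-z-scored across features;
* σ² = pooled posterior-weighted residual variance.

Because both the observations and the patterns are z-scored across F
features (norm² = F, zero mean), the Gaussian log-likelihood is linear in
the inner product x·m, and z-scoring the weighted average is exactly the
constrained M-step maximizer. EM therefore increases the log-likelihood
monotonically (asserted to 1e−6 slack); convergence is declared when the
total log-likelihood improves by less than `tol` = 1e−4 (at most
`max_iter` = 100 iterations, with a logged warning on non-convergence).
Initialization is deterministic — patterns are averaged over a uniform
segmentation of time — so fits are exactly reproducible without a seed.

**Expected-event curves and anticipation.** The curve e_v(t) = Σ_k k·γ_v[t,k]
(0-based event index) summarizes each viewing's progress through the
events. The per-viewing area under the curve (rectangle rule at TR spacing)
is converted to anticipation in seconds as

    anticipation = (mean AUC of repeated viewings − AUC of viewing 1)
                   · TR / (K − 1),

using all repeated viewings (`first_vs_rest`, default) or only the last
(`first_vs_last`). A uniform one-TR advance of all transitions yields
exactly one TR of anticipation under this scaling.

**Model-order selection.** The number of events is selected on
first-viewing data by split-half cross-validation: subjects are split into
two halves, the model is fitted to one half's mean response and scored by
log-likelihood on the other half's mean, both directions averaged, K swept
over 2..10; ties go to the smaller K. No hyperalignment is applied here so
the halves stay independent.

## Shared response model

Functional alignment uses the deterministic SRM: per subject an orthonormal
basis W_i (voxels × 10 features) and one shared timecourse S minimizing
Σ_i ‖X_i − W_i S‖² with W_iᵀW_i = I, fitted jointly over all viewings by
concatenating them in time. Block-coordinate descent alternates the
orthogonal-Procrustes update of each W_i with S = mean_i W_iᵀX_i; the
objective is non-increasing by construction and asserted in tests. S is
initialized from the first subject's top principal-component timecourses,
making the fit fully deterministic; iteration count is fixed at 30
(config-exposed). The probabilistic SRM variant is deliberately not used:
pattern averaging does not need a noise model, and determinism keeps the
permutation pipeline exactly reproducible.

## Searchlight mapping

Spherical searchlights (radius 5 voxels, stride 5, both config-exposed) are
tiled on a regular grid anchored at the mask bounding-box minimum corner
(the anchor is an explicit convention; "evenly spaced" is otherwise
underdetermined). Sphere membership is Euclidean distance ≤ radius in voxel
units, isotropic voxels assumed. A searchlight is retained if it covers at
least `min_voxels` in-mask voxels and at least `min_subjects` subjects are
valid there, a subject being valid only if every voxel in the sphere has
nonzero variance in every viewing (constant timecourses z-score to zero and
carry no signal). Each searchlight runs SRM → group averaging → joint HMM
(K = 7, matching the mean human-annotated event count of the 90 s clip) →
anticipation; failures record NaN and the run continues. Voxel maps are the
mean over covering searchlights, NaN outside coverage.

A model-free baseline cross-correlates the searchlight-mean timecourse of
the first viewing with the average repeated-viewing timecourse over integer
lags and refines the peak with the quadratic rule below; positive lag means
the repeated response leads.

## Permutation inference

Null datasets shuffle each subject's viewing order independently (uniform
permutations, default 99 nulls + 1 real run, seeded). The entire pipeline
including alignment is re-run per replicate. Voxelwise one-tailed p-values
come from a normal fit to the null values, p = 1 − Φ((real − μ̂)/σ̂), and are
thresholded with Benjamini–Hochberg FDR at q < 0.05 (step-up procedure via
statsmodels; an independent hand-rolled step-up serves as the test oracle).
The spatial-gradient test computes Spearman's rho between each selected
voxel's world-space coordinate along a chosen axis (y = posterior→anterior
by default) and its anticipation; its p-value is the add-one-smoothed
fraction of null maps whose correlation over the *same* voxel set reaches
the observed rho. For the thresholded variant the null correlations are
evaluated on the real map's significant-voxel set — the alternative
(re-thresholding each null map) can produce empty null sets.

## Boundary comparison with human annotations

Rater boundary times (seconds) are pooled into 1 s bins, convolved with a
canonical double-gamma HRF (positive lobe peaking at 6 s, undershoot
peaking at 16 s with ratio 1/6, peak-normalized to 1; all parameters
config-exposed), and linearly interpolated onto the TR grid. The model-side
boundary strength is the forward difference of the expected-event curve
(length T−1). The two are cross-correlated at integer-TR lags over the
overlapping segment only (±10 TRs by default); among local maxima the one
nearest lag 0 is selected (ties → smaller |lag|, then negative) and refined
by the vertex of the parabola through the peak and its two neighbors,
offset = ½(c₋₁−c₊₁)/(c₋₁−2c₀+c₊₁). A peak at the edge of the lag range is
reported unrefined and flagged.

Sign convention, locked by a fixture test: **positive lag = the annotation
timecourse must be shifted later to align**, i.e. the brain's boundaries
lag the annotations; brain boundaries that precede the annotations yield
negative lags. The lag shift between viewings is first-viewing lag minus
the mean repeated-viewing lag. Uncertainty over the rater panel comes from
100 bootstrap resamples of raters with replacement (95% percentile CIs for
the first-viewing lag and the mean repeated-viewing lag); replicates with
zero annotations are redrawn and logged.

## Synthetic data generator

The generator emulates the structure of the repeated-viewing experiment it
is tested against: V voxels × 60 TRs (TR = 1.5 s) × 6 viewings × N
subjects, K event patterns drawn i.i.d. standard normal and z-scored,
boundaries evenly spaced on viewing 1 and moved earlier on repeated
viewings by a controlled shift, quantized to whole TRs (data is sampled at
TR resolution; sub-TR effects are exercised through the annotation/HRF
path instead). Subject-specific structure uses random orthonormal maps (QR
of a Gaussian matrix) from a low-dimensional latent space — the regime SRM
assumes. The mixed signal is rescaled to unit RMS before noise is added so
that `noise_sd` is a noise-to-signal ratio independent of the voxel count.
Volumetric datasets place a linear anticipation gradient along one axis
(0 → `max_shift_seconds`); all subjects share the signal and receive
independent noise. Synthetic annotations keep each true boundary with
probability 1 − `miss_prob` and jitter it with Gaussian noise.

Noise is white Gaussian in time and independent across voxels. The
generator does not model temporal autocorrelation, scanner drift, motion,
physiological noise, spatial noise correlations, or HRF blurring of the
pattern timecourse. Passing tests therefore establish correctness of the
estimators under the stated generative model, not robustness to every
property of real BOLD data.

## Problem sizes and numerical choices

* Test and acceptance runs use desk-scale volumes (grids around 14×14×5,
  radius-2/stride-3 searchlights, 5 subjects, 99 permutation nulls) —
  roughly 50 searchlights and 100 full pipeline runs per inference check,
  chosen to mirror the analysis logic at a size a laptop handles in minutes.
* The SRM recovery check uses 15 subjects and a 60-voxel region at
  noise 0.5, half the original cohort size.
* The lag-estimation check uses 480-TR HRF bump trains with temporally
  smoothed noise at SNR 2: BOLD noise is autocorrelated, and temporally
  smooth noise keeps the lag-correlation curve smooth so the
  nearest-local-maximum rule behaves as it does on real data; white noise
  at the same SNR produces jagged correlation curves with spurious local
  maxima, a known fragility of the nearest-peak rule.
* Degenerate inputs: constant voxels z-score to zeros and invalidate
  subjects for searchlight inclusion; zero null variance saturates p to 0
  or 1 with a warning; constant timecourses make the lag undefined and
  raise; K = 1 posteriors are all-ones and anticipation is undefined.
* σ² is floored at 1e−12; advance probabilities are clipped to (0, 1).

## Known limitations

* σ² is shared across viewings in the joint fit (a single generative
  model); the alternative of per-viewing variances is not implemented.
* Events cannot be skipped; stimuli that genuinely omit events on some
  viewings violate the model.
* Anisotropic voxel sizes are not handled in sphere construction.
* The boundary-lag pipeline assumes both timecourses live on the same TR
  grid; the half-TR offset of forward differences is constant across
  viewings and cancels in lag shifts.
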