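# Methods

This package implements a connectome-based predictive-modeling (CPM)
pipeline for resting-state fNIRS: hemodynamic preprocessing, channel-pair
connectivity features, penalized regression of a phenotype (state anxiety)
on those features under nested cross-validation, and resampling-based
inference on both the model and its features. Because no recordings ship
with the package, every stage is exercised on synthetic cohorts with known
ground truth; this note documents the models, the defaults and their
rationale, and what the synthetic validation does and does not establish.

## Hemodynamic preprocessing

**Modified Beer–Lambert conversion.** Two-wavelength (695/830 nm) optical
density changes are converted to oxy-/deoxy-hemoglobin concentration
changes by solving the 2×2 system ΔOD(λ) = [ε_HbO(λ)·ΔHbO +
ε_HbR(λ)·ΔHbR]·d·DPF per channel and sample. Defaults: source–detector
distance d = 30 mm, differential pathlength factor DPF = 6.26 (applied to
both wavelengths), effective pathlength 187.8 mm. The extinction
coefficients are the standard tabulated molar values (695 nm: 290.0 /
1922.8; 830 nm: 974.0 / 693.04 cm⁻¹ M⁻¹ for HbO/HbR). Published
compilations differ at the percent level, so the table is explicit and can
be replaced from a delimited file (`optics.load_extinction_table`).
Concentrations are reported in µM by default.

**Trimming and artifacts.** The first and last 10 s are discarded to avoid
onset/offset transients. Motion-like artifacts are flagged automatically —
a deterministic surrogate for manual visual inspection: a sample is
flagged when the robust z-score (median/MAD) of the first difference of
either chromophore exceeds `spike_z` (default 7, chosen so a clean
Gaussian record of 4 000 samples is essentially never flagged), dilated by
`shift_window` = 5 samples. The policy for flagged spans is configurable:
keep a mask that feature extraction honours pairwise-complete (default),
linearly interpolate, or report channels whose flagged fraction exceeds a
limit (default 20%) for rejection by the caller.

**Wavelet global-noise removal.** Scalp-borne systemic physiology (Mayer
waves, respiration, slow drifts) is shared across the probe array and
inflates all channel correlations. Each channel is decomposed with an
undecimated (stationary) db4 wavelet transform; at every scale the
cross-channel mean coefficient series — the scale-wise global-component
estimate — is regressed out of each channel by per-channel least squares,
and the series is reconstructed. After the operation each channel's
coefficients have exactly zero projection onto the scale's global
estimate; a channel equal to the global component is annihilated, and
channels orthogonal to it pass through unchanged. The decomposition depth
defaults to the smallest level whose coarsest band reaches below the
analysis band's low edge (level 9 at 10 Hz for 0.01 Hz). A first-principal-
component variant of the global estimate is available
(`global_method="pca"`); the unweighted mean is the default because it is
the most direct reading of "global".

**Band-pass.** Spontaneous activity is isolated with a zero-phase two-pass
Butterworth band-pass, order 3 per pass, 0.01–0.08 Hz. The emitted QC
response is |H(f)|² (two passes); empirically a 0.04 Hz tone passes at
unit gain and a 1 Hz tone is attenuated by more than 20 dB.

Processing order is fixed: convert → trim → artifact handling → global
removal → band-pass.

## Connectivity features

Connectivity is the Pearson correlation between two channels' full
retained time courses (HbO by default; HbR by flag). No Fisher transform
is applied — the raw coefficient is the feature. For 46 channels this
gives a symmetric matrix with unit diagonal and E = 46·45/2 = 1035 unique
edges, vectorized in row-major upper-triangle order (0-based internally,
1-based channel labels in all outputs). Masked samples are excluded
pairwise-complete: each pair uses the time points at which both channels
are unflagged. Constant channels are an explicit error.

## Prediction model

Ridge regression with an unpenalized intercept, fit in closed form
(primal (XᵀX+αI)w = Xᵀy when features ≤ samples, the algebraically
identical dual/kernel form otherwise). The cross-validation scheme:

1. Participants are split into k = 8 score-stratified folds: rank by
   score, deal consecutive rank blocks of size k one-per-fold with seeded
   within-block shuffling. Every fold then spans the score distribution;
   fold sizes differ by at most one (12 each for N = 96).
2. Within each training split (84 participants), leave-one-out CV over the
   grid α ∈ {0.01, 0.02, …, 10.00} selects the α minimizing LOOCV MSE
   (smallest α on ties). The LOOCV curve for the whole grid comes from one
   SVD of the centered training matrix via the exact linear-smoother
   identity e_i = (y_i − ŷ_i)/(1 − h_ii).
3. The k selected alphas are averaged into α*; every fold's model is
   re-trained at α*; out-of-fold predictions are concatenated into one
   length-N vector; accuracy is the MSE and Pearson r of that vector
   against the observed scores.

Features enter as raw Pearson coefficients. A z-scoring toggle exists but
defaults off: the fixed grid's range is calibrated for the bounded
correlation scale, and standardizing 1035 features inflates the design
norm enough that the grid search pins at its maximum while still
under-regularizing — the model then near-interpolates and generalizes
poorly. The target is never standardized.

Fold-count sensitivity re-runs the whole scheme at k = 4, 6, 12, 16.

One design caveat worth naming: each fold's model never sees its own test
rows (verified by poisoning), but the *averaged* α* is computed from all k
training splits, so the hyperparameter — though never the weights — weakly
couples the folds. That is inherent to the mean-alpha design, which
re-trains every fold at the shared α*.

## Inference

**Permutation MSE null.** Scores are randomly re-paired with participants;
each permutation re-stratifies the folds on the permuted scores
(stratification is part of the pipeline under test) and re-runs the k-fold
fit at the fixed α*. p is the proportion of permuted MSEs ≤ the observed
MSE; the (c+1)/(P+1) convention that avoids p = 0 is available by flag.

**Bootstrap contributing edges.** B = 1000 resamples of participants with
replacement; one ridge model at α* per full resample (no CV inside the
bootstrap); per-edge percentile CI at 99% (0.5–99.5%); an edge
"contributes" when its CI lies entirely above or below zero. Degenerate
resamples (zero score variance) are redrawn and counted. The reported
per-edge weight is the bootstrap mean; the full-sample weight is also
reported. A calibration caveat measured during validation: with ample
samples per feature (n ≫ p) the CI-excludes-zero rule flags ≈1% of
pure-noise edges as designed, but in the study-scale regime (N = 96
participants, 1035 edges) the bootstrap spread of ridge weights
underestimates their true sampling variability (ratio ≈ 0.55 against a
Monte-Carlo reference), and the realized false-positive rate of the 99%
rule is ≈3–5%. This is intrinsic to percentile-bootstrap CIs for
regularized weights at n ≪ p, not an implementation artifact; edge lists
at this scale should be read as enriched, not error-controlled.

**Residual specificity.** State is regressed on trait by OLS (with
intercept) and the connectivity model predicts the residuals; a positive
out-of-fold r on residuals shows the model captures state-specific
variance not shared with trait. Degenerate cases (state ≡ trait, zero
trait variance) are explicit errors.

## Synthetic cohorts

The generator emulates the study conditions: N = 96 participants,
46 channels in 7 networks, 7 min at 10 Hz, two-wavelength intensity output
through the forward Beer–Lambert model (so the full pipeline is round-trip
testable), state scores on 20–70, trait on 22–66, state–trait correlation
0.67.

Per participant, channel signals are white noise band-passed to
0.01–0.08 Hz and mixed by the Cholesky factor of a participant-specific
correlation matrix: within-network correlation 0.3, zero across networks,
except at 15 *planted* channel pairs whose coupling u_pe varies across
participants — u_pe ~ N(0.3, 0.5) clipped to [−0.9, 0.9]. The planted
pairs and their signed effect weights (6 negative, 9 positive) follow the
contributing-edge layout of the study the generator emulates. The matrix
is repaired to the nearest unit-diagonal PSD matrix by eigenvalue
clipping. A shared band-limited (0.02–0.2 Hz) global physiological
component with per-channel gains ~N(1, 0.2²), plus white sensor noise
(15% of signal RMS), is added; HbR is −0.5 × the neural HbO signal plus
half the global component and its own sensor noise.

The inter-subject coupling spread (sd 0.5) is deliberately at the upper
end of what resting-state studies report. The identifiability argument:
edge features carry Pearson estimation noise of variance ≈0.02–0.03
(≈56 effective samples for a 0.07 Hz-wide signal over 400 s), and a
planted edge is recoverable by ridge over 1035 features only if its
cross-participant variance clearly exceeds that floor. With sd 0.5 the
planted feature variance (≈0.2) stands an order of magnitude above the
floor and the feature–latent correlation is ≈0.93.

State scores: the planted-edge combination Σ w_e·u_pe is standardized and
perturbed by N(0, anxiety_noise_sd²) (default 0.5 on the standardized
scale). Trait has two modes. `from_state` (default): trait = 0.67 × state
core + independent noise — trait then inherits a share of the connectivity
signal. `latent_factor`: trait is a standard-normal factor F independent
of connectivity, and F also feeds the state score with the coefficient
that makes the population state–trait correlation 0.67; connectivity then
drives only state-unique variance, the setting used for specificity
analyses. Scores are affinely mapped so ±2.8 SD spans the questionnaire
range, rounded to integers, clipped (clip counts are recorded in the
ground truth, never silent).

All randomness flows from one seed through spawned generators; cohorts are
bit-reproducible.

**What the synthetic validation shows — and does not.** Passing tests
establish that the pipeline recovers planted structure of realistic
magnitude under Gaussian, stationary, linear-mixing assumptions with a
single shared global component. Real fNIRS data violate several of these:
non-Gaussian motion artifacts, non-stationary physiology, heterogeneous
optode coupling, genuine inter-subject variance on *all* edges (not only
signal-carrying ones), and anatomical correlation structure richer than a
7-block community model. Results on synthetic cohorts therefore bound the
method's behavior under favourable conditions; they do not certify
performance on recordings.

## Problem sizes in tests and the acceptance script

Statistical suites run at reduced but honest sizes chosen as the package's
own validation budget: type-I calibration uses 20 null cohorts of N = 60
with 150 s recordings and P = 200 permutations; power/recovery uses 5
full-scale cohorts (N = 96, 420 s, intensity input, anxiety noise 0.05)
with P = 1000 and B = 1000; specificity uses 5 latent-factor cohorts with
180 s recordings. The acceptance script runs the full default pipeline at
study scale with P = 2000 and B = 1000.

## Known limitations

* The percentile-bootstrap edge CI is anti-conservative at n ≪ p (above).
* The wavelet global estimate assumes the global component enters every
  channel with (approximately) a scalar gain per scale; spatially
  structured physiology (e.g. regional scalp perfusion) is only partly
  removed.
* Artifact flagging is amplitude-based; slow baseline drifts within the
  pass-band are untouched.
* The channel-metadata table shipped for the 46-channel montage is
  illustrative (plausible labels and coordinates, not digitizer output);
  analyses of real probes must supply their own table.
* SNIRF containers are not read or written; all I/O is plain delimited
  text.
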