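# Methods

This note documents the models and procedures implemented in `semstory`,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## Experimental model

The unit of analysis is a story-generation *trial*: a 25 s baseline, a 5 s
word-cue presentation of a three-word target triplet, a 30 s silent
*ideation* window, and a report period. At a repetition time (TR) of 1 s a
trial spans 90 volumes and the ideation window is volumes 30–59 (0-based,
half-open). Only the ideation window is analysed neurally: it is the epoch
free of motion and vocalisation. A session has `n_conditions` (default 3:
ordinary/creative/random instructions) blocks of `trials_per_condition`
(default 8) trials, i.e. 24 stories per subject; triplet sets rotate over
conditions across subjects (`(condition + subject) mod n_conditions`), so
every triplet is seen once per subject and every set appears in every
condition at the group level. This counterbalancing is what lets group-level
decoding separate condition effects from stimulus (triplet) effects.

## Text metrics

Semantic distance of a story is the mean cosine distance between each
target word and every non-target content word, a scalar in [0, 2]; it rises
as the story's content departs from the cued words (novelty). Non-target
content words are formed by removing stop words and applying an injected
lemma map — both configuration resources, keeping the computation
language-agnostic — with set semantics (repeats counted once).
Out-of-vocabulary words raise an explicit error naming the word; a flag
permits skipping missing non-targets with a warning. Surprise is the mean
negative log-likelihood of the targets under a masked-LM distribution over
the vocabulary, in nats (natural log — the defining formula leaves the base
open; nats are the information-theoretic default). A configurable
probability floor (disabled by default) guards degenerate tables that
assign a target probability zero. Scores are computed per model and
averaged across models per story; averaging over targets and over models
commute when every model scores the same story set, which the score
aggregator enforces.

Stimulus triplets are selected by mean squared deviation of six values —
three pairwise embedding similarities (ideal 0) and three min-max
normalised word frequencies (ideal 0.5) — scanning candidates in ascending
MSE and skipping any candidate sharing a word with an earlier selection,
with at most one word per semantic category per triplet.

## Signal cleaning

Cleaning applies linear detrending, low-pass (0.09 Hz), high-pass
(0.008 Hz) and OLS confound regression in exactly that order. Filters are
order-5 Butterworth applied forward–backward (zero phase); the order is a
package choice (only the cutoffs are inherent to the procedure).
Confounds are passed through the identical detrend + filters before
regression so the residuals remain orthogonal to the confounds in the
analysed band rather than reacquiring removed frequencies. Cleaning is
linear, and a second pass changes a passband signal's interior RMS by well
under 1 %; attenuation of out-of-band components follows the squared
magnitude response of the designed filter (verified against the transfer
function). Cleaning runs per trial table before windowing. The trial-wise
sanity check computes, per condition and volume index, the sample variance
(ddof = 1) across trials, averaged over ROIs (whole brain and per network).

## Inter-subject correlation

For each ROI and triplet, the Pearson correlation of the 30-volume
ideation series is computed between every pair of subjects cued by that
triplet in the condition; the ROI's ISC is the mean of the strictly lower
triangle of the pairwise matrix, then the mean over triplets. Zero-variance
series drop their pairs with a logged count. The null distribution
circularly shifts each subject's series by an independent uniform offset in
[1, T−1] and recomputes ISC; p = (1 + #{null ≥ observed}) / (1 + n_iter)
with 5000 iterations by default. Because a circular shift of a z-scored
series only relabels time, each pair's shifted correlation is an entry of
the circular cross-correlation sequence, which the implementation computes
once by FFT and then samples — 5000 iterations cost little more than one.
Circular shifting preserves each series' power spectrum, so the null keeps
single-subject autocorrelation structure while destroying alignment.

Condition contrasts difference the per-triplet ISC maps (every triplet has
an ISC in both conditions thanks to the rotation) and build the null by
sign-flipping the per-triplet differences, 5000 iterations, two-sided;
BH-FDR q-values are attached. With few triplets the sign-flip null is
coarse (minimum two-sided p ≈ 2/2^k for k triplets), which matters for
small synthetic designs.

## Group searchlight MVPA

Samples are all subjects' ideation volumes of the two conditions,
concatenated. Units are feature-column sets (by default one per ROI; on
parcellated data a unit holds one column — a `min_features` threshold can
skip thinner units). Folds are five repetitions of a stratified 50 % split
of whole trials; a trial's volumes never straddle the split. Features are
z-scored with training-fold statistics. Classification uses an RBF-kernel
SVM with C = 1 and accuracy scoring; regression uses OLS with a
cross-validated R² score and a rank-based median split of the target for
fold stratification.

The permuted baseline re-runs the full procedure on exchangeable
relabellings: each of `n_label_permutations` (default 100) draws permutes
whole-trial labels globally and re-derives its own stratified folds.
Re-deriving folds is essential — reusing folds stratified on the true
labels biases the baseline below chance, and drawing within-fold
permutations independently per repetition under-disperses the null
relative to the real statistic. *Performance* is the mean cross-validated
score minus the mean baseline score.

Two inferential quantities are reported per unit:

- `p_f`: the 5 × 2 cv F-test of the real against the pooled-baseline fold
  scores, F = (Σ_ij p_ij²)/(2 Σ_i s_i²) referred to F(10, 5). Zero
  variance of the differences is a flagged degenerate case (p = 1). A
  per-permutation variant (F against each permutation's folds, averaged)
  sits behind `baseline_scheme`.
- `p`: an exact permutation p of the mean cross-validated score against the
  per-permutation scores, (1 + #{perm ≥ real})/(1 + M). This is the
  calibrated quantity and the one BH-FDR (at α = 0.01 and 0.05) is applied
  to. The F(10, 5) reference is not calibrated for decoding-vs-baseline
  comparisons: all ten fold differences share the dataset-conditional
  chance decodability of a finite trial sample, and fold scores correlate
  within a repetition, neither of which its iid assumption allows; in null
  simulations this inflated its rejection rate several-fold at any problem
  size, while the permutation p rejects at the nominal rate. For a discrete
  permutation p, rejection at level α means p ≤ α.

## Connectome harmonic decomposition

The template vertex connectome combines (i) long-range links: the region ×
region tract matrix (donor-averaged if a stack), symmetrised as
(M + Mᵀ)/2 and binarised at the mean of all entries, with vertex pairs of
connected regions linked; and (ii) local links between vertex pairs closer
than 10 mm. The graph must be connected (components are reported
otherwise). Harmonics are the eigenvectors of
Δ_G = D^{-1/2} (D − A) D^{-1/2}, computed by full symmetric
eigendecomposition, eigenvalues ascending in [0, 2]; the zero mode
(eigenvector ∝ D^{1/2}·1) is retained and its window membership is the
first window. Signs are fixed (first non-negligible entry positive) for
reproducibility; within degenerate eigenspaces ties are ordered by the
sign-fixed vectors, and windowed energies are insensitive to rotations
within a pair only when the window covers the pair (exact for summed
squared energy; verified on the ring's paired modes). A vertex signal
projects as ω = F Φ; reconstruction and Parseval hold to 1e−6 with the
full basis.

Windowed spectra use window length round(0.04 · n) and step round(0.02 · n)
— 205 harmonics for a 5124-vertex basis — giving ⌊(n − w)/s⌋ + 1 windows
ordered by spatial frequency. "Energy" defaults to the mean |ω_k(t)| per
window; squared and eigenvalue-weighted variants are available, as the
aggregation is a modelling choice rather than a fixed definition.

## Functional connectivity and temporal irreversibility

FC is arctanh(Pearson r) per ROI pair and story, averaged over a
participant's stories; |r| is clipped at 1 − 1e−7 (divergence guard,
negligible bias). Summaries average within-network (i < j) or
between-network pairs for DMN/SAN/FCN; the diagonal is excluded
everywhere; a top-k % edge extraction supports contrast maps.

Irreversibility compares the lagged correlation of a zero-meaned pair,
C_f(τ) = corr(x_i(t), x_j(t + τ)) on the overlapping T − τ samples (each
segment re-centred), with the same quantity C_r(τ) on the time-reversed
series; R(τ) = (C_f − C_r)². Each ordered pair is computed independently;
note that time reversal maps C_r(i, j) onto C_f(j, i), so R is symmetric
by identity — the asymmetry information lives across lags, not across the
pair ordering. Lags run 1–15 (the longest still leaves T − 15 = 15 samples
at T = 30); story-averaged tensors per participant are summarised as short
(1–7) and long (8–15) lag-cluster means, a full R(τ) curve, and
edge-level paired-t contrasts at an uncorrected threshold (default
p < 1e−4).

## Inference utilities

Paired comparisons use the one-tailed paired t-test; Cohen's d defaults to
mean difference over the SD of the differences, with an average-SD variant
(the two conventions differ and both are reported in the literature
without always being named). The 95 % CI of d inverts the noncentral-t
distribution at the observed t. Identical inputs return t = 0, p = 0.5
(no evidence either way); constant non-zero differences are a degenerate
error. BH-FDR is the step-up procedure (via statsmodels), validated
against a brute-force enumeration; Bonferroni rejections are always a
subset of BH rejections.

## Synthetic data: what it emulates and what it does not

The generator plants, inside the ideation window only: (i) smooth
(Gaussian-filtered, unit-variance) time courses fixed per triplet and
shared across subjects, scaled per ROI — the minimal structure ISC
detects, with an optional per-condition gain for contrast ground truth;
(ii) deterministic condition mean patterns separated by
`condition_pattern_strength[r]` per adjacent condition index, alternating
sign across ROIs (deterministic so a planted ROI always separates);
(iii) noise with a block network covariance (equicorrelated within-network
blocks, PSD by construction) or unit-variance iid noise; (iv) lagged
linear autoregressive couplings `x[t, target] += gain · x[t − lag, source]`
— the minimal mechanism producing forward/reverse asymmetry. Baseline,
cue and report volumes are unstructured noise. Heavier-tailed (Student-t)
noise is available for robustness checks. All draws flow from a single
seeded generator; identical design + effects + seed give bit-identical
tensors.

Not emulated: haemodynamic response convolution, scanner drift and
physiological confounds, spatial autocorrelation between ROIs beyond the
planted covariance, voxel-level structure (the pipeline operates on
parcellated/vertex signals by design), and any linguistic realism in the
toy lexicons and LM tables. Passing tests therefore establish the
*statistical machinery* — estimator correctness, null calibration,
sensitivity to planted effects, counterbalancing behaviour — not the
neuroscientific conclusions one would draw on real recordings.

Validation problem sizes (for example 6 subjects × 4 trials × 30 volumes ×
20 ROIs for chance calibration, 250 two-ROI simulations with 19-permutation
nulls for type-I error, 1000-replicate Monte-Carlo oracles for
irreversibility) are chosen as the smallest designs at which the planted
effects and calibration properties are unambiguous.

## Known limitations

- The triplet count is parameterised rather than fixed (the stimulus
  selection naturally yields a configurable number of admissible triplets);
  the default design uses 3 × 8 = 24.
- The sign-flip contrast null requires several triplets to reach small
  p-values; very small designs saturate at 2/2^k.
- The 5 × 2 F-test p (`p_f`) is reported for fidelity to the procedure it
  implements but is anticonservative for decoding-vs-baseline nulls; use
  the permutation p for inference.
- Whether cleaning should run per run or per trial before windowing is a
  configuration decision; the default cleans each trial table as provided.
- The NIfTI adapter is a thin optional path (mean over voxels per atlas
  label) and is not exercised by the default test suite.
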