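# Methods

This note documents the models, conventions and design choices behind
`burntex`, in the order the pipeline applies them.

## Images and co-occurrence matrices

Images are integer grids with `L` quantized grey levels (default `L = 256`,
i.e. 8-bit B-mode exports are used as-is, with no histogram requantization).
Coordinates are 0-based `(row, column)` from the top-left corner, so the row
index increases with imaging depth.  RGB input is converted with the
BT.601 luma weights — a convenience only, since B-mode exports are already
greyscale.  An optional `levels < 256` rescales raster input by
`floor(v·L/256)`; CSV matrices are taken as already quantized.

The co-occurrence matrix for offset `(k, l)` counts **ordered** pairs
`(I(m,n), I(m+k, n+l))`; it is not symmetrized by default (the transpose
equals the negated offset, and a `symmetric=True` option adds it).  Pixels
whose offset partner falls outside the image are skipped — no wraparound or
padding — so for offset `(0, 1)` an `M×N` image yields exactly `M(N−1)`
pairs.  The default offset is `(0, 1)` (horizontally adjacent pixels);
construction is `O(MN)` via a flattened bincount.

Features are computed from the **normalized probability form**
`p(i,j) = χ(i,j)/Σχ`, not raw counts.  Most features are scale-invariant
either way; standardizing on probabilities makes images of different sizes
comparable.  All entropy-family quantities use the **natural logarithm**
with `0·log 0 := 0`.  The base is one global constant: it rescales the
entropy features uniformly (harmless under min–max normalization) and
cancels inside the information measures of correlation when used
consistently.

## Texture features

The catalog implements 20 second-order statistics (see the table in
`burntex/features.py`); the default active set holds 19 of them, excluding
the plain-normalized inverse difference whose role duplicates the
moment-normalized variant.  Conventions that have more than one definition
in circulation are fixed globally:

- **difference variance** is the variance of the `|i−j|` distribution
  `p_{x−y}` (not the alternative "variance of `(i−j)²` weights" reading);
- **homogeneity** weights by `1/(1+(i−j)²)` and **inverse difference** by
  `1/(1+|i−j|)` — the two local-similarity measures differ only in the power
  of the weight;
- **IMC-II** is `sqrt(1 − exp(−2(H_{XY2} − H_{XY})))`, clamped at zero
  before the square root so floating-point noise cannot produce a NaN; the
  argument `H_{XY2} − H_{XY}` is the mutual-information-like quantity that
  grows with (possibly nonlinear) dependence between neighbouring pixels;
- a constant image makes correlation undefined (`σ_x σ_y = 0`); batch
  extraction must not crash, so correlation returns 0.0 and the feature
  vector carries a warning flag.

Feature columns are min–max normalized to `[0, 1]`,
`(x − min(x)) / (max(x) − min(x))`, per dataset.  A constant column maps to
zeros rather than NaN (it carries no information but downstream classifiers
must still run).  **Inside any cross-validation loop the (min, max) pair
comes from the training fold only** and the held-out sample is transformed
with those statistics *without clipping*: the independence of the left-out
observation extends to its scaling, at the cost of occasional values outside
`[0, 1]`.

## Sequential backward selection

SBS starts from the full feature set; each stage evaluates every
single-feature removal with the criterion — the mean pairwise LOOCV accuracy
over all class pairs, weighted equally **per pair** (six pairs for four
groups), not per sample — and commits the best removal.  Termination is on
**strict decrease**: removals that leave the criterion unchanged are allowed
and favour smaller sets, since a feature whose removal does not change the
accuracy is redundant.  Ties between equally good removals go to the feature
earliest in the fixed catalog order.  Both rules make the trace
deterministic and independent of the sample ordering, which the tests
assert.  The criterion curve is non-decreasing from the full set through the
final stage by construction.  Being greedy, SBS does not explore all `2^d`
subsets; the tests bracket its final criterion between the full-set value
and the exhaustive-search optimum on small catalogs.

## Classifiers

**Pairwise RBF-SVM.**  The null-hypothesis group is labelled +1, the other
−1; a soft-margin SVM with RBF kernel (scikit-learn's `SVC`) is fitted on
the normalized training features.  The signed decision value is the
classification score: positive means the sample is assigned to the
null-hypothesis group.  Hyperparameters are nowhere prescribed by the
problem, so the defaults are the reproducible, leak-free choices `C = 1` and
`γ = 1/(d · Var(X_train))` (the "scale" heuristic, recomputed per training
fold); both are exposed for sweeping.

**KFDA.**  The kernelized Fisher criterion — maximize projected
between-class scatter over within-class scatter in the RBF feature space —
reduces to the generalized eigenproblem `M α = λ N α` on the `n×n` kernel
matrix, with `M = Σ_c n_c (m_c − m)(m_c − m)ᵀ` and
`N = Σ_c K_c(I − 1/n_c)K_cᵀ`.  `N` is rank-deficient by construction, so a
ridge `ε·I` is mandatory; the default `ε = 10⁻³ · trace(N)/n` scales with
the data, and a genuinely singular system raises with advice to increase it.
The top `C−1` eigenvectors give the discriminant scores `s₁…s_{C−1}`
(sign-fixed by making the largest-magnitude coefficient positive, so reruns
are identical).  Classification is nearest class centroid in score space
with Euclidean distance; exact ties go to the class earliest in
first-appearance order.  With a very wide kernel the leading discriminant
recovers classical Fisher LDA up to scale, which the tests verify as a
correlation > 0.99 on 2-class Gaussian data.

## Evaluation protocols

LOOCV refits *everything* — normalization statistics and classifier — on
each fold of `n−1` samples and evaluates the held-out one; the confusion
matrix aggregates all folds and accuracy/sensitivity/specificity are
computed from the aggregate.  Multiclass per-class accuracy is the
row-normalized diagonal (recall).  Report display rounds to two decimals,
half-up; raw ratios are preserved internally.

Monte-Carlo evaluation draws repeated mutually exclusive train/test splits
(default 90/10, 100 repetitions).  Splits are **stratified per class** —
plain random splitting can empty a class of ~30 samples, which would make
KFDA ill-posed — and driven by a single integer seed, so a rerun reproduces
every per-repetition accuracy exactly.

The minimum-sample-size formula
`n = max(z² sₙ(1−sₙ)/(d²P), z² s_p(1−s_p)/(d²(1−P)))` returns the ceiling of
the larger branch: the sample sizes needed to estimate sensitivity (among
the prevalent fraction `P`) and specificity (among `1−P`) to within margin
`d` at confidence `z`.  `P ∈ {0, 1}` is rejected (division by zero), and a
perfect anticipated test (`sₙ = s_p = 1`) legitimately needs 0 samples.

## Synthetic phantoms

The generator emulates the qualitative appearance of thermally damaged
tissue in B-mode imaging: dark speckle regions (grey band ≈ 0–70) that
increase in number and size with severity and appear progressively along
depth.  It makes no attempt at acoustic field simulation.

- **Background:** the envelope of a spatially smoothed complex Gaussian
  field — Rayleigh-amplitude speckle with a controllable correlation length
  (σ = 3 px) — scaled to mean grey 120.  Display dynamic-range compression
  is mimicked by damping envelope fluctuations to 35% around the mean;
  without it the raw Rayleigh texture is so contrasty that darkening lesions
  would *lower* absolute contrast, inverting the expected trends.
- **Damage:** a Poisson number of elliptical blobs, expected count
  `3.5·10⁻³ · s` per pixel and mean radius `2.5 + 1.5 s` px for severity
  `s ∈ [0, 1]` (both affine in `s`, so blob count and size are
  non-decreasing in severity; `s = 0` yields pure background).  Blob centres
  are restricted below a depth-onset row at fraction `0.5(1−s)` of the image
  height.  Each blob multiplies the image by `1 − a·w` with peak attenuation
  `a ∈ [0.5, 0.8]` and a flattened (super-Gaussian) radial profile `w`,
  placing blob interiors in the dark 0–70 band.
- **Interior texture:** inside blobs the smooth background envelope is
  replaced by a finer-grained envelope whose correlation length shrinks with
  severity (`1.0 − 0.2 s` px).  This is the mechanism that makes damaged
  regions *decorrelate* the local texture: contrast, difference variance,
  IMC-II and sum entropy rise with severity while correlation, homogeneity,
  inverse difference and maximum probability fall — the eight signature
  trends of the selected feature set, which the tests assert as strictly
  monotone per-class means over the severity ladder (0, ⅓, ⅔, 1).

The default image size is 160×120 px, a scaled-down stand-in for the
~250×190 px field of a 1.5×1.1 cm frame at ~59 µm resolution; it keeps the
full default dataset (4 × 30 images) generating and classifying in seconds
while leaving the GLCM dense enough at `L = 256`.  The default dataset uses
30 images per class, matching the ~33-per-group scale of realistic *ex
vivo* protocols.  Parameters were chosen so adjacent middle severities
overlap slightly (pairwise LOOCV accuracies of 0.95–1.00) rather than
separating perfectly, because that is the regime in which an evaluation
protocol is actually informative.

**What the phantoms do not capture:** physical speckle statistics of real
probes (fully developed speckle, attenuation with depth, TGC), anatomical
layering (epidermis/dermis/fat interfaces), shadowing and reverberation
artifacts, inter-subject variability, and any histological ground truth.
Passing phantom tests therefore demonstrates the pipeline's correctness and
its sensitivity to the modelled texture signatures — not clinical
performance on real burn images.

## Numerical choices and degenerate inputs

- Probability sums are validated to 1 within 1e−9; feature oracles agree to
  1e−10 on random 4×4 distributions.
- `ceil` in the sample-size formula subtracts 1e−9 first so that values
  that are integers up to floating-point noise are not rounded up twice.
- Empty manifests, duplicate paths, zero-pair co-occurrence matrices,
  single-class KFDA input, folds that would empty a class, and crop
  rectangles outside the image all raise immediately with the offending
  object named; nothing is silently clamped or imputed.
- Seeds: every stochastic component (phantom generation, Monte-Carlo
  splits) is driven by explicit integer seeds; per-image seeds are spawned
  deterministically from the dataset seed.

## Known limitations

- SBS is a greedy heuristic; it cannot guarantee the globally optimal
  feature subset (the exhaustive bound is only checked at small `d`).
- KFDA decision rule is nearest-centroid in score space; class-conditional
  covariance in score space is ignored.
- LOOCV with per-fold refits is `O(n)` classifier fits per evaluation and
  `O(n·d)` for SBS stages; fine at `n ≈ 150`, but quadratic kernel matrices
  make KFDA impractical beyond a few thousand samples.
- The inner grid search for SVM hyperparameters mentioned as an option is
  not implemented; `C` and `γ` are fixed, documented defaults.
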