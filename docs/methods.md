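# Methods

## Overview

`msinmf` implements a cohort-level analysis pipeline for mass
spectrometry imaging (MSI) in the negative-mode lipid range. The method
has five stages:

1. **Preprocessing** — each dataset's centroided spectra are binned onto
   a fixed m/z grid, truncated to the information-dense low-mass range,
   and TIC-normalized per pixel.
2. **Joint decomposition** — all tissue pixels of all datasets are
   stacked into one matrix `I (N × M)` and factorized as `I ≈ Z Ψ` with
   nonnegative spectral components `Ψ (m × M)` shared across the cohort
   and nonnegative spatial loadings `Z (N × m)` per pixel. A PCA baseline
   is provided for comparison.
3. **Classification** — per-dataset loading cubes are cut into
   non-overlapping patches; patches are flattened, class-balanced, split
   80/20, and classified with grid-search-tuned linear/RBF SVMs (F1 of
   the positive CPH class).
4. **Component ranking** — two orthogonal rankings: backward elimination
   by reconstruction error, and an iterative candidate-list procedure by
   contribution to classification accuracy.
5. **Registration and rendering** — H&E histology images are aligned to
   spatial component maps by color segmentation, Canny edges and an
   ECC-maximizing homography; thresholded maps are color-coded and summed
   into composite "H&E-like" images.

## Models and formulas

**TIC normalization.** For pixel (x, y) of dataset d with binned
intensities `I_{x,y,s}`, the normalized spectrum is
`Ĩ_{x,y,s} = I_{x,y,s} / Σ_s I_{x,y,s}`; tissue pixels therefore sum to
exactly 1 and zero-total pixels are flagged off-tissue rather than
raising. Normalized cubes are stored in float64: the per-pixel sums are
then exact to ~1e-15, whereas float32 storage would leave ~6e-8
round-off in the sums, which matters because TIC conservation is one of
the package's hard guarantees.

**NMF.** The factorization minimizes the squared Frobenius loss
`Σ |Ĩ − Z Ψ|²` subject to `Z, Ψ ≥ 0`, solved by scikit-learn's
coordinate-descent (HALS-type) updates. Initialization is the
deterministic nonnegative double-SVD variant (`nndsvda`, the library
default); random-uniform initialization is available but lands in
measurably worse local optima on cohort-sized problems. Working
precision inside the solver is float32 (`solver_dtype`), standard at
this scale; all reported errors are accumulated in float64.

**Reconstruction error.** Throughout, the normalized error of a
component subset `S` is the ratio of sums of squares
`err(S) = Σ (I − Z_S Ψ_S)² / Σ I²` — a fraction in [0, 1], reported as a
percentage by the acceptance script. Backward elimination evaluates
`err(S)` for every single-component removal at every step; the package
expands the error into cached Gram-matrix terms (`Z'Z`, `ΨΨ'`,
`diag(Z'IΨ')`, `ΣI²`) so each candidate subset costs O(m²) instead of a
full data pass. Tests cross-check the closed form against the direct
blockwise computation and against an independent brute-force greedy
oracle.

**Accuracy-based ranking.** With `P` the smallest per-dataset patch
count, every evaluation draws exactly `P` patches per dataset (the
anti-bias guarantee against unequal tissue sizes), restricts patch
vectors to the candidate component set, and records mean stratified
5-fold CV accuracy of a linear SVM (fixed C = 1, chosen for speed and
interpretability over the 50 × N inner fits). Fifty redraws (default)
give a distribution per candidate; the best-mean component plus every
component statistically indistinguishable from it (Welch two-sample
t-test, p ≥ alpha = 0.05, no multiplicity correction — documented
choice, the procedure is selection not inference) join the candidate
list. Iterations stop when the candidate list alone reaches 75% mean
accuracy; exhausting all components is flagged, not raised. Seeds are
derived per (iteration, component, repeat), so the inner fits are
order-independent and safely parallelizable.

**ECC registration.** The enhanced correlation coefficient between a
fixed image and a warped moving image is the zero-mean normalized
correlation, invariant to affine intensity rescaling of either input.
The optimizer is the forward-additive Gauss-Newton ECC iteration on the
eight homography parameters, run as a three-stage scale-space schedule
(Gaussian smoothing at 4σ, 2σ, σ with σ = 1 by default, full resolution
throughout, up to 500 iterations and eps = 1e-6 per stage). Scale-space
continuation replaces a decimation pyramid deliberately: component maps
are small rasters with near-periodic ring structure, and decimation
leaves too few pixels while encouraging lock-on to the wrong ring. A
non-positive ECC-update denominator (uncorrelated images) or hitting the
iteration cap flags the result instead of raising, so best-pair
selection can still compare scores. `warp` always maps moving-image
coordinates to fixed-image coordinates; `apply_warp` resamples
accordingly with bilinear interpolation.

Precision note: on noise-free planted homographies with corner
perturbations up to 5% of image width, alignment of intensity maps
recovers corners to well under 1 px. Alignment of binary Canny edge maps
carries an extra 1–3 px of edge-relocation error on rasters this small;
edges remain the production path across modalities (H&E segment vs
component map) because they are robust to the intensity distribution
mismatch, and their ECC scores are what best-pair selection compares.

**Color segmentation.** ROI statistics drop per-channel outliers beyond
3 scaled MADs of the median before computing mean and SD; the segment is
all pixels within mean ± 2 SD in every channel. With a degenerate
(uniform) ROI the MAD is zero and only median-valued pixels survive,
which removes lone extreme pixels while keeping a uniform ROI intact.

**Composite imaging.** Each selected map is thresholded (Otsu by
default, overridable), normalized to [0, 1] by its own maximum,
multiplied by a color vector in [0, 1]³ and by the display scale (255),
and the layers are summed and clamped to [0, 255] as uint8 — never
wrapped. A warning fires when more than 1% of pixels clamp.

## The phantom generator

The study's raw animal data are not deposited, so the generator emulates
the study design with full ground truth: D = 8 datasets, 4 per class
("CPH" vs "naive"), rasters intentionally unequal (36–48 px per side) so
patch-count equalization is actually exercised.

**Spatial templates** (20 components by default): 6 concentric annuli
(radii 0.15R–0.9R of the tissue disk R = 0.46·min(A, B), Gaussian
profile σ = 0.40R/6), 12 Gaussian blobs sunflower-packed in the
0.25R–0.9R annulus (σ = 0.14R), one diffuse component covering the
whole disk, and one off-tissue/matrix component outside it. Geometry is
identical across datasets up to per-dataset amplitude jitter U(1 ± 0.05);
this is deliberate: any per-dataset geometric signature would let a
patch classifier identify the source dataset and leak class labels even
under a null effect.

**Spectral templates**: 8 peaks per component in 600–1100 Da — 6 unique
positions (≥ 0.35 Da apart, so distinct 0.05 Da bins) plus 2 minor peaks
(damped ×0.2) from a 12-peak shared pool; heights U(0.3, 1), then
L1-normalized so loadings carry the abundance scale.

**Class effect**: the diffuse component's amplitude is multiplied by
1.8 in CPH datasets. The choice of a *diffuse* marker is load-bearing:
TIC normalization keeps only compositional information, so an abundance
shift on a component that exclusively owns its pixels disappears after
normalization. A diffuse marker shifts the composition of every tissue
pixel — consistent with the method's working assumption that
class-separating compounds are distributed throughout the tissue — and
with the ×1.8 default puts held-out patch F1 in the ~0.85–0.95 range on
fitted maps rather than at ceiling.

**Noise**: Poisson counts on the planted peak intensities at ~8000
expected counts per pixel, 12 background peaks per pixel with
exponential intensities (mean 1) at uniform m/z over the full 600–2000
Da range (so truncation removes real signal-free mass), and a ±20%
multiplicative per-pixel TIC jitter which only TIC normalization can
undo — making the normalization step load-bearing in every downstream
test. Counts and background were set during generator design so that 20
components suffice for the 20 planted sources; with much lower counts,
the collective Poisson noise of the large matrix region out-competes
the smallest planted blobs for components.

**H&E-like images**: region labels (dominant component per pixel,
evaluated analytically at 4× resolution) are painted in distinct palette
colors on a near-white background, lightly noised, and warped by a
random homography whose corner displacements stay within 5% of the map
width; the warp (at map scale, moving → fixed) is part of the ground
truth.

**What the phantom does not emulate**: biophysically realistic lipid
spectra, isotope envelopes, mass-accuracy drift, instrument noise
physics, spatially correlated acquisition artifacts, within-class
anatomical variation beyond amplitude jitter, and true H&E stain
chemistry. Passing tests therefore demonstrate the pipeline's
correctness and its statistical behavior under the planted model, not
performance on real tissue.

## Problem sizes and budgets

All defaults match the standard parameters (0.05 Da bins over 600–2000
Da, truncation at 1100 Da, m = 20, iteration cap 6000, 20 px patches,
80/20 split, 50 repeats, 75% stopping accuracy). Phantom-scale analyses
in the tests and the acceptance script make three documented scale
choices:

- **NMF iterations**: on the ~13,800 × 10,000 phantom stack the
  coordinate-descent objective plateaus (~0.15% residual) within a few
  dozen iterations; fits run with `max_iter=200`. The 6000-iteration cap
  remains the module default for full-scale cohorts.
- **Patch width 10** (instead of 20) on phantom maps: the phantom's
  36–48 px rasters are an order of magnitude smaller than real slide
  rasters, and w = 10 keeps per-dataset patch counts (12–16) in a regime
  where stratified 5-fold CV and balanced splits are well defined.
- **Ranking repeats 10** (instead of 50) for the multi-seed recovery
  studies; the discriminative component's margin over noise components
  is large enough that 10 repeats decide the first candidate reliably.

Two further study-design notes: the 20-seed discriminative-recovery
study ranks the generator's *compositional ground-truth maps*
(`GroundTruth.normalized_z`) — the noise-free analogue of fitted maps —
because refitting NMF per seed is pointless for a test of the ranking
procedure itself; conversely the null-effect chance-level check uses
*fitted* maps from one null cohort, because noise-free ground-truth maps
contain near-duplicate patches across classes that push CV accuracy of a
margin classifier systematically below chance (an artifact of exact
duplicates, absent from any estimated map).

## Numerical choices and edge cases

- Bin edges are half-open `[mz_min + s·w, mz_min + (s+1)·w)` anchored at
  `mz_min`; a peak exactly on an edge belongs to the right bin; peaks at
  or beyond `mz_max` are dropped and counted in the log.
- Bin intensity is the **maximum** peak intensity in the bin.
- Zero-total pixels are masked off-tissue, never an error.
- Backward-elimination ties break toward the lower component index.
- Welch's t-test handles unequal variances; two identical zero-variance
  samples count as p = 1 (both selected).
- Balanced splits down-sample the majority class at random under the
  given seed; `round(train_frac · n)` per class go to train.
- `best_alignment` ties break toward the lexicographically lower
  (map index, segment index); flagged alignments keep their score and
  stay in the comparison.
- Singular warps raise; out-of-frame warp pixels are zero-filled.
- Patch grids anchor at the image origin; partial border patches drop;
  patches with under 80% tissue coverage drop (configurable).

## Known limitations

- The ECC optimizer assumes the initial overlap is within the coarse
  smoothing's basin of attraction (~5% of image width); gross initial
  misalignment needs an external initialization (`init=` parameter).
- Edge-map alignment precision is limited by Canny edge relocation on
  small rasters (see above).
- The accuracy-based ranking inherits the patch-augmentation caveat that
  patches of one dataset appear on both sides of the inner CV splits, so
  its accuracies are internal selection scores, not generalization
  estimates across animals.
- `fit_pca` uses randomized SVD for large inputs; components are
  deterministic under the given seed but not bit-identical across BLAS
  builds.
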