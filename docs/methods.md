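# Methods

This note documents the models and procedures implemented in `tumorherd`,
the defaults chosen where the design was open, and what the synthetic test
bed does and does not establish.

## Phantom generator

Each slice is a schematic axial brain image on a 224×224 8-bit grid:

* **Brain** — an ellipse with half-axes 0.85/0.70 of the image half-size,
  base intensity 95 with smooth (σ = 8 px) ±6 intensity variation, on an
  air background of 10.
* **Tumor** — a star-shaped region: an ellipse whose radius is perturbed
  sinusoidally, `r(θ) = r0·(1 + a·sin(kθ + φ))`, with 3–6 lobes. The
  relative amplitude `a` is the `boundary_irregularity` parameter. The
  target area is drawn uniformly from the interior of
  `tumor_area_range` (a fraction of image area) and the radius is
  iteratively rescaled so the realized pixel area always lies inside the
  range. Tumor intensity is 185 plus low-pass-filtered Gaussian texture
  (σ = 2.5 px) scaled to `tumor_texture_contrast`. The center is sampled
  so the lesion lies strictly inside the parenchyma — gliomas do not cross
  into air.
* **Class defaults** — class 1 (LGG-like): area 2–5 %, irregularity 0.08,
  texture contrast 16; class 2 (HGG/GBM-like): area 5–12 %, irregularity
  0.18, contrast 30. Class 2 dominates class 1 on every axis, which is
  the separation the classifier is asked to learn. Values were fixed once
  to give watershed-detectable lesions with realistic relative sizes
  (a GBM occupying up to ~26 % of the brain ellipse).
* **Skull** — optional annulus of thickness 4–7 px at intensity 230 ± 10
  hugging the brain boundary, emulating non-skull-stripped T2 slices.
* **Noise** — additive zero-mean Gaussian, clipped to [0, 255]; the
  robustness experiments use σ = 15.

Same parameters (including seed) ⇒ bit-identical slice. The generator
makes no attempt at radiometric MRI realism: no bias field, no partial
volume, no k-space artifacts, single 2D slices only. Consequently, passing
tests demonstrate the pipeline's mechanics and its noise robustness on
this geometry — not clinical performance.

Dataset splits use floor rounding for validation/test and give the
remainder to training, so 1500 per class at (0.8, 0.1, 0.1) yields
1200/150/150.

## Segmentation

CLAHE enhancement (default clip 1.0 on the OpenCV-style scale = skimage
clip limit 0.01, 2×2 tiles) followed by marker-controlled watershed:

1. morphological open/close (disk radius 2) to flatten texture;
2. Sobel gradient of the flattened, lightly blurred (σ = 1.5) image as the
   flooding landscape — internal-texture ridges must not exceed the lesion
   boundary ridge, otherwise neighboring basins conquer the lesion;
3. three-class Otsu split (air | parenchyma | bright structure); bright
   components adjacent to air (skull annulus, rim artifacts) are removed —
   a glioma sits inside parenchyma;
4. fragments of one lesion are merged by closing; ring-shaped components
   are left unfilled (filling a skull ring would swallow the brain);
5. internal markers = the distance-transform core (≥ 40 % of peak depth)
   of each bright component with at least `marker_size` = 10 px; an area
   marker claims the interior, which single-pixel seeds often lose;
6. external markers: the image frame (air) and eroded parenchyma
   components — without a tissue marker the lesion basin floods the brain;
7. candidate basins are filtered (area ≥ 30 px and ≤ 25 % of the image,
   solidity ≥ 0.4, not air-adjacent) and the one with the highest mean
   enhanced intensity is kept (FLAIR/T2 gliomas are hyperintense);
8. post-processing: hole fill, largest component, border clear — an
   idempotent map; an empty mask is a legal output.

Defaults were validated on 50 random seeds per condition (2 classes ×
skull × clean/noisy): mean Dice 0.95–0.99 clean and ≈ 0.99 at σ = 15,
with zero skull overlap. Two defaults differ from the obvious first
choice, both for verified reasons: CLAHE tiles 2 (not 8) because 28-px
tiles fully contain a lesion and equalize away its hyperintensity, and
clip 1.0 (not 2.0) because stronger equalization pushes tumor-free brain
tiles to near-saturation, creating rival bright patches that outrank small
low-grade lesions.

Noise helps CLAHE+Otsu slightly (dithering), which is why noisy Dice can
exceed clean Dice; the clean-image failure mode is threshold placement on
sparsely populated histograms, not boundary accuracy.

## Features

* **GLCM (25)** — computed on the *grayscale* crop of the mask's bounding
  box, quantized to 8 levels; symmetric, normalized matrices. Layout:
  {contrast, correlation, energy, homogeneity, entropy} × {0°, 45°, 90°,
  135°} at distance 1 (20 values), plus the same five statistics on the
  direction-averaged matrix at distance 2 (5 values). Entropy is Shannon
  entropy in bits of the normalized matrix. The binary mask itself feeds
  only the shape block: co-occurrence statistics of a binary region are
  nearly degenerate.
* **Hu (3)** — the first three of the seven invariant moments of the
  binary mask, reported as `sign(h)·log10|h|` (0 ↦ 0) to tame their
  ~10-order-of-magnitude dynamic range. Translation/rotation invariance is
  exact to numerical precision; 2× rescaling agrees to ~1e-3 on the log
  scale (discretization).
* **Deep (1000)** — the `DeepExtractor` contract: a deterministic map from
  a 224×224×3 slice to a 1×1000 vector. The built-in `StubExtractor`
  mean-pools channels, block-averages to 32×32, and applies a fixed seeded
  Gaussian random projection to 1000 dimensions. It is a weight-free
  deterministic embedding that preserves coarse geometry (lesion size,
  brightness), sufficient for the phantom classes; it is *not* a learned
  representation, and results with it say nothing about pretrained-CNN
  transfer quality.

All 1028 feature names (1000 deep + 25 GLCM + 3 Hu) are unique, keeping
fused coordinates traceable.

## Elephant-herding optimization

A clan-structured population metaheuristic (maximization convention):

* member update toward the clan best: `X_new = X + a·(X_best − X)·r`,
  with `a, r ~ U(0,1)` drawn per dimension;
* matriarch update: `X_new = β·X_center` (clan centroid), β default 0.1 —
  β is a free parameter here; a small drift keeps the centroid update from
  teleporting clans;
* separation: once per generation block (`max_iter / n_generations`
  iterations) the worst member of each clan is replaced by
  `X_min + (X_max − X_min + 1)·rand`. The `+1` makes the literal formula
  overshoot the upper bound; the sample is clamped, preserving the bounds
  invariant while keeping the published update intact;
* elitist global best; every evaluated position lies in bounds; fixed
  iteration budget (default 1500, 30 members in 5 clans).

## Feature selection

The 2-D search position is `(q, ρ) ∈ [0,1]²`. Per-feature **Cartesian
distance (CD)** scores are |class-mean difference| of each z-scored
column (zero-variance columns score 0). Candidates are features with
score ≥ the q-quantile; a greedy pass in descending score order drops any
candidate with |Pearson correlation| > ρ to an already-kept feature (ρ is
evaluated on a 0.01 grid, which also makes the objective cacheable).
Selection never returns empty: the argmax-CD feature is the fallback.

Fitness is the Euclidean distance between class centroids in the selected
standardized subspace divided by `k^(1/4)` (k = subset size). A `√k`
penalty would make fitness the RMS of per-feature gaps, which is maximized
by the single feature with the largest empirical gap and collapses the
selection to one feature; the quartic-root penalty prefers keeping all
comparably informative features while still rejecting noise (a marginal
feature must contribute a gap² of roughly half the current average to be
worth keeping). With 5 planted features (standardized shift 2.0) among
100 and 300 samples per class, the search recovers ≥ 4/5 planted with few
noise features in ≥ 9/10 seeded runs.

The published reduced dimensions (373/416 FLAIR, 401/428 T2) are
dataset-specific outcomes of this kind of search, not targets; reduction
is applied per network before fusion.

## Fusion, classification, metrics

Fusion is ordered concatenation with per-part provenance; dual-deep and
DL+ML dimensions follow as sums (373+416 = 789, 401+428 = 829,
373+25+3 = 401, 401+25+3 = 429). Standardization is fitted on training
rows only (zero-variance columns pass through centered) — distance-based
classifiers would otherwise be dominated by the 1000-dim deep block.

Classification uses stratified three-fold CV with in-fold scaling;
class 2 (high-grade) is the positive class. Frozen defaults: logistic
regression (C = 1), Gini decision tree (unlimited depth), 100-tree random
forest, KNN (k = 5, Euclidean), RBF-SVM (C = 1, γ = 1/d). Per-fold and
pooled confusion counts are both reported; the best fold is identified
(ties → lowest index) because the source protocol reports best-fold
numbers, but pooled counts are the headline here — best-fold reporting is
optimistically biased.

Metrics are the five percentages AC/PR/SE/SP/F1S, held at full precision
and displayed with half-up rounding at the 4th decimal; undefined
denominators are reported as undefined, never as 0 or 100. F1S equals the
harmonic mean of PR and SE algebraically. AUC is trapezoidal with midrank
tie handling.

## Numerical and degenerate-input policy

* Constant images: CLAHE is the identity; watershed returns an empty mask.
* Empty masks in the pipeline: the GLCM/Hu block is imputed as zeros and
  the slice is flagged in the report.
* Empty candidate sets in selection: argmax-CD fallback, never an error.
* Non-finite objective values abort the EHA run with an error.
* Seeds: every stochastic component takes an explicit seed; derived seeds
  stay below 2³¹.

## Problem sizes

The shipped experiments use 150 slices per class end-to-end, 50 phantoms
per segmentation condition, 20 optimizer runs, and 5–10 selection runs —
sizes at which every behavior of interest (convergence, recovery, Dice
robustness, ≥ 95 % pooled accuracy) is already stable on one CPU.

## Known limitations

* The phantom is geometric, not radiometric; claims transfer to real MRI
  only qualitatively.
* The stub extractor is not a CNN; plugging in real backbones (and any
  fine-tuning) is intentionally out of scope.
* The watershed candidate scoring assumes a hyperintense lesion (FLAIR/T2
  convention); hypointense-lesion modalities would need a different
  ranking.
* The published per-network reduced dimensions and the headline accuracies
  on clinical archives are not reproducible without those archives and
  pretrained weights; the package reproduces the *arithmetic* of every
  published metric and dimension exactly, and the pipeline's behavior on
  phantoms.
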