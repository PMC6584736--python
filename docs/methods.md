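# Methods

This note documents the models, conventions, parameters and deliberate
design choices behind the package, and what the synthetic phantoms do and do
not establish about real MR data.

## Input model

An ROI is a rectangular-parallelepiped 3D scalar volume (`VoxelGrid`) with
per-axis physical spacing in mm. Anisotropy is expected: the in-plane
spacing of the motivating acquisition setting is 1.04–1.56 mm with 3.0 or
3.5 mm slices, and default phantom spacing (1.2, 1.2, 3.0) mm mirrors that.
Intensities are arbitrary units; both tracks begin by mapping them linearly
and continuously (no rounding) onto [0, 255]. A constant volume normalizes
to all zeros with a warning — any constant is equivalent for both tracks.

## Texture track

### Preprocessing chain

Order is filter → resample → quantize. Each stage is one axis of the
240-member extraction-parameter grid (5 × 6 × 4 × 2).

* **Wavelet band-pass** — one-level separable 3D coiflet-1 decomposition
  with symmetric padding; the six mixed sub-bands (LLH … HHL) are scaled by
  R, LLL and HHH keep weight 1, and the volume is reconstructed at its
  original shape. The weights are deliberately un-normalized so R = 1 is the
  identity (perfect reconstruction), the one property of the filter that is
  independently checkable.
* **Isotropic resampling** — trilinear interpolation onto an isotropic
  lattice. The "native" grid entry resamples only z down to the in-plane
  spacing; the others use 1–5 mm cubes. Physical extent is preserved to
  within one voxel per axis; samples beyond the last voxel center clamp to
  the edge value.
* **Quantization** — two scalar quantizers to Ng ∈ {8, 16, 32, 64} levels.
  *Equal-probability* is implemented rank-based (level = ⌈Ng · ECDF(v)⌉):
  bins sit at empirical quantiles, levels are as equally populated as ties
  permit, and the output is exactly invariant under any monotone intensity
  transform — a property interpolated quantile edges would not give.
  *Lloyd–Max* runs centroid/boundary alternation from equal-probability bin
  means until the largest centroid move is below 1e-6 of the intensity
  range (max 100 iterations); degenerate level collapse is reported.

### Features

43 features in fixed order: 3 global moments computed on the filtered,
resampled, **unquantized** intensities (quantizing first would discard the
moments' information), then four matrix families on the quantized grid:

* **GLCM** (9): a single co-occurrence matrix summed over the 13 unique 3D
  directions at displacement 1, symmetrized and normalized. One merged
  matrix rather than per-direction averaging keeps small ROIs away from
  degenerate matrices. Correlation is defined 0 when the marginal variance
  vanishes (constant input).
* **GLRLM** (13): run-length matrix merged over the same 13 directions.
  Run Percentage is normalized by voxels × directions so it stays in (0, 1]
  for the merged matrix.
* **GLSZM** (13): zones are maximal 26-connected equal-level components
  (`scipy.ndimage.label`); Zone Percentage uses plain voxel count.
* **NGTDM** (5, Amadasun–King): 26-neighborhood means, edge voxels use the
  neighbors that exist. Coarseness carries an ε = 1e-6 denominator guard so
  constant input stays finite; the Busyness denominator Σ|i·p_i − j·p_j| is
  treated as zero below 1e-10 (it vanishes analytically whenever the
  level-weighted occupancies coincide).

The exact formula dialect of the matrix statistics varies across the
radiomics literature; the definitions used here are the standard published
ones (Haralick, Galloway, Thibault, Amadasun–King) and every one of them is
pinned by an independent brute-force enumerator in the test suite, so the
implemented dialect is fully specified by executable oracles rather than
prose.

### Extraction-parameter selection

For each of the 43 features, all 240 parameter combinations are scored by
the mean over stratified bootstrap resamples of |Spearman ρ| between the
feature and the binary label; the argmax wins, ties breaking by fixed grid
enumeration order (R, iso, Ng, algorithm). The absolute value is used
because a strongly negative monotone association is exactly as useful to a
linear discriminant as a positive one. Default 1000 replicates; stratified
resampling preserves class counts so no resample loses a class.

Selection on the full cohort **before** LOOCV reproduces the original
procedure and is the default ("faithful" mode); it leaks label information
into the evaluation. The "nested" mode re-selects inside every training
fold and is the statistically safer variant; both are exposed because the
gap between them is itself informative.

## Topology track

Sublevel filtration with **dark foreground** (voxel present iff value ≤ h):
tumors are dark on the motivating images, so lesions birth early. The
cubical complex is the vertex construction — voxels are vertices; each
edge/square/cube spanning adjacent voxels enters at the **max** over its
incident voxels. This makes degree-0 classes exactly the 6-connected
components of the binarized volume, which is the connectivity the validation
oracles (union-find component counts, Euler cell census) assume and verify.

Pairs are computed by GF(2) boundary-matrix column reduction in filtration
order (sorted by value, then dimension so faces precede cofaces), processed
from dimension 3 downward with the clearing optimization, numba-compiled.
Zero-lifetime pairs are dropped — they carry weight arctan(0) = 0 in any
persistence image. The single essential degree-0 class (a full box is
contractible, so no degree-1/2 essentials can occur) is recorded with death
255.5, keeping diagrams inside the square [−0.5, 255.5]². Volumes above
300,000 voxels are refused without an explicit override, matching the
largest ROI scale the method is intended for.

## Persistence images

ρ is evaluated at the cell centers of a mesh × mesh grid over
[−0.5, 255.5]² (no within-cell integration — at the default 256 the cells
are one intensity unit wide) and flattened row-major, birth axis first. The
weight parameters satisfy C > 0, p > 0, σ > 0. Defaults C = 1, p = 1,
σ = 4; when searched, the candidate grid σ ∈ {1, 2, 4, 8}, C ∈ {0.01, 0.1,
1}, p ∈ {1, 2} spans sharp-to-smooth kernels over the 0–255 domain, and the
search objective is five-fold cross-validated accuracy of the downstream
classifier — the parameters exist only to serve classification. Essential
pairs participate at death 255.5 (configurable to drop them).

## Classification

* **Elastic-net LDA** is realized as penalized optimal scoring: elastic-net
  regression of a ±1 class indicator, objective
  1/(2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²), thresholded at the midpoint of
  the training class-mean scores and squashed through a logistic link so the
  output reads as a probability. This is the standard sparse two-class LDA
  reduction.
* **Elastic-net logistic** uses the saga solver; **boosted trees** use the
  histogram method, single-threaded for bit-reproducibility.
* Default grids: λ log-spaced over 1e-3…1e2 with α ∈ {0.1, 0.5, 0.9};
  tree depth {2, 3} × learning rate {0.1, 0.3} × rounds {50, 200} — a
  small-N regime; all configurable, and a single-candidate grid skips the
  inner search.
* Features are standardized with training-fold statistics only; the decision
  threshold is fixed at 0.5 rather than tuned (a tuned threshold would
  inflate the reported operating point); AUC is the Mann–Whitney statistic.
* LOOCV runs N fits, each excluding one lesion; the held-out label is never
  visible to fitting or to the inner grid search (tested explicitly).

## Phantom generator

Each phantom is a bright background (level 0.78 of the intensity range)
carrying a Gaussian random field — white noise smoothed by a Gaussian kernel
of width `correlation_length_mm`, expressed per axis in voxels so anisotropy
is respected, rescaled to `background_sd` — plus planted dark structures
(level 0.04 of the range) and i.i.d. voxel noise, clipped to the intensity
range. Structures are placed by rejection sampling away from the walls and
from each other; failure to place after 200 tries sets an `overlap_warning`
provenance flag rather than erroring.

* **Blobs**: solid ellipsoids (semi-axes 2–4 mm) — degree-0 content.
* **Rings**: solid tori in the xy-plane, major radius 4.5–6.5 mm, tube
  radius ≥ 0.6 × the coarsest spacing, with centers snapped to slice
  centers so a 3 mm slice spacing cannot miss the tube — one degree-1 class
  each.
* **Cavities**: spherical shells ≥ 1.4 × the coarsest spacing thick with a
  bright core — one degree-2 class each.

With zero noise and non-overlapping structures, the number of degree-1
(degree-2) pairs with lifetime above half the dark/background contrast
equals the planted ring (cavity) count exactly; this is a tested invariant.
Cohorts derive per-item seeds from a `SeedSequence` of the cohort seed and
jitter each item's shape by ±15–25 % per axis to emulate lesion-size
variation. Default shapes (~5,000–10,000 voxels) sit in the small-to-middle
range of real ROI sizes (the motivating study spans ~1,200–224,000 voxels);
voxel counts are validated against [1,000, 250,000].

What phantoms do **not** emulate: MR physics (T1/proton-density contrast),
anatomically shaped lesions, partial-volume and bias-field effects,
inter-scanner variation. Passing the phantom-based tests establishes the
correctness of the machinery (filtration, reduction, feature algebra,
selection, cross-validation hygiene) and the recoverability of planted
class signal — not clinical accuracy on patient data.

## Study conditions used by the acceptance script and heavy tests

Scaled to desk size as the package's own defaults: cohorts of 25 lesions
per class at shape (26, 26, 11) voxels; ring-bearing class (2 tori) vs a
control with matched dark content (2 ellipsoids) so that per-volume
normalization cannot separate the classes by intensity range alone and the
class signal is genuinely topological; noise SD 10, background field SD 6;
persistence-image mesh 64 with σ = 4 for classification experiments;
single-candidate hyperparameter grids where the inner search is not itself
under test; texture runs on a 24-member sub-grid of the 240 (3 ratios × 2
isotropic sizes × 2 level counts × both quantizers) with 100 bootstrap
replicates. Under these conditions degree-1 persistence images classify the
ring cohort at ≈ 0.95–1.0 accuracy while degree-2 images on the same cohort
sit at chance — the degree-dependence the method predicts, since the cohort
carries no cavity signal.

## Known limitations

* The wavelet family/level and the texture-formula dialect of the
  motivating MATLAB lineage cannot be recovered exactly from public
  descriptions; the choices above are pinned by tests rather than by
  reference output.
* Faithful selection mode leaks labels by construction (it reproduces the
  original procedure); use nested mode for unbiased estimates.
* The persistence engine targets ROI-scale volumes (≲ 3 × 10⁵ voxels), not
  whole-organ grids.
* `ElasticNetLDA` probabilities are calibrated only up to a monotone map;
  AUC and the 0.5-threshold operating point are unaffected, but the scores
  are not posterior probabilities.
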