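# Methods

## Pipeline model and assumptions

The package classifies subjects from the *texture* of DTI scalar maps
(MD, FA, RD) inside a segmented ROI.  Its core assumptions:

- The maps are already registered to a common grid and the ROI mask is
  given.  Tensor fitting, eddy-current correction, skull stripping,
  registration and segmentation are upstream of this package; when tensor
  eigenvalues are available, `scalar_maps_from_eigenvalues` applies the
  standard closed forms (MD = mean eigenvalue, RD = mean of the two minor
  eigenvalues, FA = normalized eigenvalue dispersion).
- Class-relevant information is captured by the *distribution* of local
  gradient structure within the ROI, not by voxelwise correspondence
  across subjects.  This is what makes the bag-of-words representation
  appropriate: subjects yield different keypoint counts per slice, and the
  K-bin signature histogram is a fixed-length summary invariant to keypoint
  order and count.
- Sensitivity/specificity follow the convention that the *more impaired*
  class is positive (AD in AD-vs-NC and AD-vs-MCI; MCI in MCI-vs-NC).

## Stages and tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| slicing axis | 3rd array axis (axial) | — | configurable to sagittal/coronal; slice-wise 2-D detection keeps the standard descriptors applicable |
| `min_roi_pixels` | 16 | voxels/slice | a slice needs enough ROI area to support stable keypoints |
| rescale percentiles | (1, 99) | % of in-ROI intensities | robust 8-bit quantization; constant slices map to 128 |
| SIFT | 3 scales/octave, σ₀ = 1.6, contrast 0.04, edge ratio 10, ×2 upsampling | — | the literature-standard constants |
| SURF Hessian threshold | 100 | 8-bit intensity², area-normalized | standard operating point for 8-bit input |
| SURF octaves | 4 (filter sizes 9–195 px) | px | standard pyramid; images smaller than three filter sizes of an octave skip that octave |
| vocabulary size K | 100 | words | small enough to estimate from ~10³–10⁴ training descriptors per fold, large enough to resolve texture modes |
| `m_selected` | min(p, 50) | features | Fisher-ranked bins retained before the SVM |
| SVM grid | C ∈ 2^{−2..8}, γ ∈ 2^{−10..2} (steps of 2²), inner 3-fold | — | standard log₂ grid; fixed (C, γ) can bypass the search |
| folds | 10, stratified, seeded | — | reduced with a warning when the smallest class is smaller |

Keypoints whose center falls outside the ROI mask are discarded; their
descriptor windows may overlap the zeroed background, which is
uninformative by construction.  Quantization assigns each descriptor to the
Euclidean-nearest centroid with ties to the lowest index; subjects with
zero features receive an all-zero signature and a logged flag rather than
exclusion.

## Leakage discipline

Every training artifact — the k-means vocabulary, the Fisher ranking, the
standardizer and the SVM (including its hyperparameter search) — is fit on
the training portion of each fold only; test subjects are quantized against
the training fold's vocabulary.  A deliberately leaked variant
(`codebook_scope="global"`, vocabulary built on all subjects) exists because
small-sample studies sometimes do this implicitly; it is flagged in the
report and never the default.  The test suite verifies bit-for-bit that
replacing test-fold subjects with noise leaves a fold's training artifacts
unchanged.

## Fusion

"Feature-level fusion" is read as pooling the three maps' *descriptor sets*
into one clustering problem (descriptors share a dimension, one K-bin
signature per subject).  The alternative reading — concatenating three
per-map K-bin histograms into a 3K vector — is implemented as
`fusion_mode="histogram_concat"`, since either is defensible.
Decision-level fusion takes the modal label of the three per-map
classifiers; when all three disagree (possible only in multiclass), the RD
map's vote arbitrates — the natural generalization of the stated
two-maps-disagree/RD-decides rule.  Multiclass decision fusion is provided
but flagged, as the rule is defined for binary problems.

## The phantom generator

`dtibow.synthetic` emulates one abstraction of real cohorts: *within-ROI
texture statistics differ by class*.  Each subject is baseline (MD
0.7×10⁻³ mm²/s, FA 0.35, RD 0.5×10⁻³ mm²/s) plus 2 % Gaussian acquisition
noise; inside an ellipsoidal ROI a band-limited random field
(Gaussian-smoothed white noise, unit variance over the ROI) is added with
class-specific contrast (10/15/20 % of baseline for NC/MCI/AD), granularity
(4.0/2.4/1.4 voxels) and mean shift (0/5/10 %, diffusivity up and
anisotropy down with impairment).  `effect_scale` interpolates all class
parameters toward their across-class mean (0 ⇒ a null cohort);
`map_split` confines or distributes each class's signal across the three
maps, enabling carrier-map and split-signal (fusion) designs.

Because every slice is percentile-rescaled before descriptor extraction,
absolute levels and amplitudes are largely normalized away; the signal the
descriptors actually see is the texture length-scale and the
texture-to-noise ratio.  The generator therefore demonstrates that the
pipeline recovers *texture-statistic* class differences — it says nothing
about whether real neurodegeneration produces such differences, and it does
not attempt biophysical realism (no fibre geometry, no partial volume, no
registration error, no scanner effects).  Passing tests on phantoms bound
the pipeline's correctness, not its clinical performance.

## Numerical choices

- Negative tensor eigenvalues beyond −10⁻⁹ are clamped to 0 with a warning
  (noise-floor convention); FA is clipped to [0, 1].
- The Fisher-score denominator uses population (ddof = 0) class variances
  and a 10⁻¹² floor; ranking ties break to the lower feature index.
- k-means: k-means++ initialization, single initialization with a fixed
  seed, ≤ 300 iterations, relative-inertia tolerance 10⁻⁴; empty clusters
  are relocated to the farthest points.
- SURF keypoints are localized on the pixel grid (no subpixel/scale
  interpolation): the downstream signature uses only the descriptor, and
  the invariance benchmarks show grid precision suffices at the 2 px
  matching tolerance.
- ROC curves sweep all unique decision values; AUC is trapezoidal and
  equals the Mann–Whitney pairwise statistic.  Per-fold standard deviations
  use ddof = 1.  Undefined metrics (empty margin) are NaN, never 0.

## Problem sizes

Desk-scale experiments use a 64 × 64 × 24 grid with 30 subjects per class
(the package's scaled-down analogue of the emulated 96-subject study with
its 256 × 256 × 59 acquisition matrix), K = 100 and 10 folds; unit tests
use 48 × 48 × 16 grids, the smallest on which both detectors' scale
pyramids operate in the central ROI crops (~25 px across).

## Known limitations

- SURF at the smallest octave needs ≥ 21 px of in-plane ROI; very small
  structures on coarse grids yield no features and are flagged.
- The per-fold vocabulary makes cross-validation O(folds) more expensive
  than a leaked global vocabulary; this is intentional.
- 3-D (volumetric) keypoints, soft assignment, TF-IDF weighting and spatial
  pyramids are out of scope, as are non-SVM classifiers.
- With very few descriptors per training fold, K must be lowered by the
  caller; the codebook constructor refuses K larger than the descriptor
  pool.
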