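# Methods

## The fusion model

`entrofuse` treats ensemble fusion of binary volumetric segmentations
as a weighted-average problem. Each model contributes a per-voxel
value m_j(v) ∈ [0, 1] — a binary mask or a probability map, both are
accepted — and the fused score is the convex combination
P(v) = Σ_j w_j m_j(v), binarized at an inclusive threshold t (default
0.5). The weights come from the entropy weight method: each model's
calibration performance is summarized as an ordered metric vector,
the vector is normalized to a distribution p_i = m_i / Σ_l m_l, and
its Shannon entropy H = −Σ p_i log₂ p_i is converted to a weight
w_j ∝ 1 − H_j, renormalized to sum to one.

Assumptions baked into this design:

* **Weights are global per model** — one scalar per model per
  ensemble, not per slice or per voxel. The weighting expression
  indexes weights by model only.
* **The metric-to-distribution step is scale-invariant**: multiplying
  all metrics by c > 0 leaves H, and hence the weights, unchanged.
* **Calibration and target data are distinct roles.** The caller
  decides which labeled volumes calibrate the weights; the package
  does not prescribe a validation/test split.

### Entropy conventions

With L metrics, the raw entropy lies in [0, log₂ L] bits, so for
L > 2 a near-uniform metric vector drives H above 1 and makes 1 − H
negative. The default `normalized` convention divides by log₂ L,
keeping H ∈ [0, 1] and every 1 − H term non-negative. The `raw_bits`
mode computes the literal bit-valued entropy; it is guarded by the
degenerate-denominator fallback: when |Σ_k (1 − H_k)| ≤ ε (default
ε = 1e-9) the weights are ill-conditioned and the ensemble falls back
to uniform weights, flagged `degenerate` in the output.

### A known quirk of entropy weighting on similarity metrics

The method rewards *peakedness* of the metric profile, not its level.
A perfect model scores 1.0 on every similarity metric, which is the
uniform distribution — maximal entropy — and therefore receives the
*minimum* weight, while a model whose metric vector is lopsided (for
example an all-background predictor: precision 1 by the empty-set
convention, recall 0) has low entropy and receives a large weight.
With models of broadly similar, good quality the weights land near
uniform and the method behaves like a slightly tilted average, which
is the regime it is intended for; with models of very unequal quality
the entropy ordering need not follow the quality ordering. The
package implements the formulas faithfully and surfaces entropies and
weights in logs and reports precisely so users can audit this.

A second structural fact worth knowing: with exactly two models whose
inputs are binary masks, the thresholded fusion at t = 0.5 equals the
higher-weighted model's mask whenever the weights are unequal, and the
union of the masks when they are exactly equal (ties included on both
sides by the inclusive rule). Fusion of binary inputs is therefore
most informative with near-equal weights, or with more than two
models, or with probability maps as inputs.

### Numerical choices

* Confusion counts are exact integer tallies; every ratio metric is a
  single float division of integers, so results are bit-reproducible.
* Empty-set convention: similarity metrics with a zero denominator
  return 1.0; undefined per-class terms are excluded from per-slice
  means so slices without foreground stay well defined.
* `m_IoU` defaults to the global aggregation, (JI_F + JI_B)/2 on
  whole-volume counts; a `per_slice` mode (mean over z-slices of the
  slicewise class-IoU mean) is provided because reported mean-IoU
  values in the literature are often slicewise and the two do not
  coincide.
* AUROC uses the tie-corrected rank (Mann–Whitney) formulation:
  exact, threshold-free, and identical to the all-pairs definition;
  for binary scores it reduces to (TPR + TNR)/2.
* Binarization uses the inclusive rule (score ≥ t → 1) so that the
  two-model equal-weight case recovers the union of the input masks.
* Normalized weights must sum to 1 within 1e-6 when passed to
  `fuse`; fused scores are clipped to [0, 1] (reachable only with
  negative raw-bits weights).

## Preprocessing

CLAHE and Gaussian blur run per 2D z-slice (their parameters — tile
grids, 3×3 kernels — are 2D notions). Defaults: clip limit 2 on an
8×8 tile grid, 3×3 blur. The clip limit follows the OpenCV-style
convention (a multiple of the mean histogram bin height) and is
mapped to scikit-image's normalized clip as `clip / nbins` with
nbins = 256. The blur kernel is assembled explicitly with
σ = 0.3·((k−1)/2 − 1) + 0.8 (σ = 0.8 for k = 3, the common
derive-from-kernel-size convention) and applied with reflect padding,
so constant slices are reproduced exactly and the interior impulse
response equals the kernel. Intensity volumes are interpreted in one
of two declared domains — 8-bit [0, 255] or normalized [0, 1] — and
outputs stay inside the input's domain.

A geometric slice-alignment stage is represented by a pass-through
hook (`align_slices`): no transform model, reference frame, or
parameters are fixed for it, so it is the identity and exists so
pipelines can name the stage.

## The phantom generator

`generate_ground_truth` emulates what matters for testing fusion and
metrics: disjoint foreground objects of the two mitochondrial
morphologies, ovals (axis-aligned ellipsoids, per-axis radii drawn
from `radius_range`, centers on the voxel grid) and tubes (random-walk
centerlines of `tube_length_range` steps, dilated by a spherical
element). Objects are placed by rejection sampling with a clearance
of `min_gap ≥ 1` voxels against the 26-connected dilation of the
existing foreground, which guarantees exactly `n_objects` 26-connected
components. Defaults (32×64×64 volume, 6 objects, radii 2–5 voxels,
tube lengths 8–20) give a foreground fraction of a few percent —
comparable to the sparsity of mitochondria in EM volumes at a coarse
voxel scale.

`degrade` applies, in order: whole-object drops (each component
independently with `object_drop_prob`), boundary erosion/dilation by
a spherical element of |`boundary_radius`|, Poisson-distributed
false-positive blobs constrained never to touch (26-connectivity) the
true foreground so FP/FN accounting in tests is unambiguous, and
i.i.d. voxel flips. The `simulate` command's default two-model
ensemble uses drop probability 0.15, boundary radius ∓1 (one model
under-, one over-segments), one expected FP blob and flip probability
5e-4 — error magnitudes chosen to mimic the behavior of strong but
imperfect networks, where whole-object misses dominate the Dice loss.

What the phantoms do *not* emulate: electron-microscopy texture and
intensity statistics, anisotropic voxels, touching organelles,
spatially correlated (non-i.i.d.) noise, and membrane-like thin
structures. Tests passing on phantoms therefore certify the algebra
and mechanics of fusion and evaluation, not segmentation quality on
real micrographs.

Every generator derives its random stream from (seed, operation name),
so repeat calls are bit-identical regardless of call order.

### The complementary-false-negative experiment

The mechanism the fusion exists to repair is reproduced exactly:
two otherwise-perfect predictions each missing disjoint whole objects
are fused with weights calibrated on a phantom of identical spheres
(each model missing one), which makes the two calibration metric
vectors — and hence the weights — exactly equal at 0.5/0.5. Every
voxel predicted by either model then reaches the inclusive 0.5
threshold, the fused mask equals the union of the predictions, and
the union equals the truth by construction, so fused Dice is exactly
1.0 while each individual Dice is below 1. The acceptance suite
verifies this over 100 phantom seeds (12×28×28 volumes, 4 objects),
and `scripts/acceptance.py` re-measures it over 50 seeds.

## Problem sizes

The test suite and the acceptance script run on volumes between 1³
and 24×48×48 voxels with up to 8 objects — large enough that every
morphology, degradation mode and aggregation path is exercised, while
the full suite completes in seconds. The metric implementations
themselves are vectorized and scale to arbitrarily large volumes.

## Known limitations

* The entropy-weighting quirk described above: weight order follows
  metric-profile peakedness, not model quality.
* CLAHE's exact output depends on the underlying tile interpolation
  implementation; only its contracts (determinism, range and shape
  preservation, constant-input invariance) are guaranteed, not
  bit-identical agreement with other CLAHE implementations.
* No boundary-distance (Hausdorff, surface-Dice) or instance-level
  detection metrics; no DICOM/NIfTI I/O; no anisotropic resampling;
  single foreground class only.
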