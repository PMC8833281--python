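# Methods

## Problem and model

During template-based interstitial gynecologic HDR brachytherapy, 15–20
hollow plastic catheters are implanted trans-perineally and must be
digitized ("reconstructed") on the planning MR images before dwell
positions can be placed. Marker-filled plastic catheters are hyperintense
on 3D T1-weighted images and appear as signal voids on 3D T2-weighted
images; both contrasts are acquired in one exam and are treated as
co-registered. `cathrecon` implements a two-stage semiautomatic
reconstruction:

1. **Segmentation.** One 2D U-net per contrast, trained on square axial
   patches with a soft-Dice objective, produces a per-pixel catheter
   probability map for every slice. Pixels with probability strictly
   greater than 0.5 are catheter candidates.
2. **Deterministic tracking.** Starting from manually seeded positions on
   the template plane (slice *m*), the algorithm walks slice by slice
   toward the tip. On each slice, 8-connected components of the binarized
   mask become candidates; each candidate is localized on the intensity
   image inside a small rectangle; candidates from the two contrasts are
   fused; each tracked catheter takes its nearest fused candidate within an
   8-pixel neighborhood (greedy, one-to-one; surplus candidates are false
   positives). A catheter with no candidate in reach is a *jumping
   catheter*: its position is imputed by adding the per-axis mean of the
   **absolute** displacements of the detected catheters,

       dx = (|x1' - x1| + ... + |xk' - xk|) / k,   and likewise dy,

   to its previous position. Tracking stops per catheter at the slice
   implied by its physical insertion depth: `total length - (free length +
   template thickness)`, divided by the slice thickness (axial insertion
   assumed). This free-length rule guarantees one complete path per seed —
   a catheter can be imputed but never lost.

Agreement between two reconstructions is measured on *dwell positions*: 3D
points resampled at 1 mm arc-length intervals along each path. Each dwell is
scored by its distance to the nearest point of the other path's polyline,
and summarized by mean ± SD, the fraction below 2 mm (the clinically cited
tolerance) and above 3 mm, the Dice coefficient of the rasterized paths,
and the symmetric point-set Hausdorff distance.

## Network

The segmentation network is the classic symmetric U-net: per encoder level
two 3×3 convolutions + ReLU followed by 2×2 max pooling; per decoder level
a 2×2 stride-2 transposed convolution + ReLU, concatenation of the matching
encoder feature map, and two 3×3 convolutions + ReLU; a 1×1 convolution +
sigmoid head. With five levels a 128×128 input reaches 8×8 at the
bottleneck. With the full-scale widths (64, 128, 256, 512, 1024) the
closed-form trainable-parameter count (Σ k²·c_in·c_out + c_out) is
31,030,593; the package's `build_unet` descriptor and the allocated arrays
agree exactly, by construction and by test.

The engine is written directly in NumPy (im2col + BLAS matmul, float32,
hand-written gradients verified against finite differences) — the network
is small enough that a framework is unnecessary, and this keeps the package
dependency-light and fully deterministic. Design choices where the method
description is open:

- **Optimizer: Adam** (β₁ = 0.9, β₂ = 0.999). The reference training recipe
  fixes the learning rate (1e-5), He-normal initialization, 100 epochs and
  batch size 8, which remain the package defaults; desk-scale
  configurations use reduced widths (8–128), 10 epochs and a learning rate
  of 1e-3, under which the phantom task converges in minutes on one CPU.
- **Smoothed Dice.** The loss is `1 − (2Σpt + ε)/(Σp + Σt + ε)` with
  ε = 1.0 in both numerator and denominator, so the empty-vs-empty case is
  defined (loss 0) and division by zero cannot occur.
- No batch normalization, no dropout, no early stopping; a validation set,
  when given, is only logged (per-epoch soft Dice).
- Skip connections merge by channel concatenation.
- Training patches are 64×64, class-balanced: half centered (with ±4 px
  jitter) on labeled catheter-component centroids, half at uniformly random
  background positions — balance prevents the all-background minimum.
  Optional augmentation draws translation ±8 px, scale 0.9–1.1, rotation
  ±15° per epoch; pixels and label receive the identical affine and the
  label is re-binarized at 0.5.
- Inference tiles each slice with overlapping windows (default 64 px, 32 px
  overlap, edge windows shifted inward rather than padded) and averages
  overlapping predictions.

## Tracking parameters

| parameter | default | meaning |
|---|---|---|
| `neighborhood_px` | 8 | linking radius around the previous-slice position (voxels) |
| `rect_halfsize` | 5 | refinement rectangle half-width (~2.7 mm at 0.53 mm pixels) |
| `merge_tolerance_px` | 2 | max distance for fusing a T1W with a T2W candidate |
| `min_component_size` | 1 | smallest mask component kept (1 = keep all) |
| `refine_mode` | `"region"` | candidate localization on the intensity image |
| `signed_jump` | off | use signed instead of absolute mean displacements |
| `arc_length_stop` | off | stop by accumulated 3D path length instead of slice count |

`refine_mode="region"` thresholds the rectangle halfway between its median
and its extremum, keeps the 8-connected component nearest the candidate,
and returns that component's centroid; this averages over the whole
catheter cross-section and is robust to single-pixel noise.
`refine_mode="extremum"` instead returns the single brightest (T1W) /
darkest (T2W) pixel, with ties broken by distance to the candidate and then
row-major order; it is exposed because it is the simplest reading of
"find the extrema", but the region centroid is the default precisely
because the extremum of a flat-topped cross-section under noise is a
~1-pixel-noise estimator, which measurably degrades dwell accuracy.

Two behaviors are deliberate extrapolations of the written rules: (i) the
absolute-value form of the jump correction is implemented verbatim even
though it biases corrections toward +row/+col when detected catheters move
in opposing directions (the signed variant sits behind `signed_jump`), and
(ii) when *every* catheter jumps on a transition, the mean displacement is
undefined (denominator is the number of detected catheters), and positions
are carried over unchanged (Δ = 0).

## Synthetic phantom

No imaging data are distributed with the package; all experiments run on a
generated phantom that emulates the salient image characteristics:

- paired volumes, default 96×96×40 voxels at 0.5327×0.5327×1.0 mm;
- catheter tracks as smooth in-plane random walks (Gaussian steps low-pass
  filtered along the slice axis, per-slice step ≤ `curvature`, default 1
  voxel/slice, entering at a template plane and ending at a tip implied by
  a per-catheter insertion length of 28–34 mm (so tracks span most of the
  40-slice volume); tracks are redrawn until all pairs keep ≥ 2 radii + 2
  voxels of same-slice separation, since real catheters are solid and
  cannot overlap;
- rendered cross-sections as anti-aliased disks (default radius 2 in-plane
  voxels ≈ a 6F catheter at 0.53 mm pixels — an estimate; the true diameter
  in voxels is not specified anywhere and is a free parameter), **added**
  in T1W (+4 by default) and **subtracted** in T2W (−4), on a base of
  smoothed-noise tissue texture;
- dark ellipsoidal "air cavities" (dark in both contrasts, the classic
  void confounder), placed away from the tracks;
- additive Gaussian noise (SD 0.5 against catheter contrast 4).

The phantom is bitwise reproducible from its seed. What it does *not*
model: MR physics (bias fields, k-space artifacts, sequence-dependent
contrast), anatomy, registration error between contrasts, marker
heterogeneity along the catheter, and metal or tandem applicators (out of
scope for the method itself). Passing phantom tests therefore demonstrates
the correctness and stability of the algorithmic chain — not clinical-grade
segmentation performance, which depends on training with real cohort data.

## Evaluation choices

- Deviations use nearest-point-on-polyline rather than index-paired dwells:
  index pairing would charge a purely longitudinal sampling offset as
  lateral error. A `paired=True` mode exists for sensitivity checks.
- The terminal path point is always included in a dwell set even when the
  last interval is < 1 mm, because tip position is clinically salient.
- Path DSC rasterizes both path sets with the same disk radius used for
  training labels (default 2 voxels).
- Per-dwell deviations are pooled across catheters (per-catheter summaries
  are also reported); Hausdorff is computed per catheter on dwell points
  and averaged.
- Histogram export uses 0.25 mm bins from zero.

## Problem sizes used in tests

The test suite and the acceptance script run entirely on phantoms sized for
a single CPU: 10-catheter, 40-slice phantoms; networks with widths
(8, 16, 32, 64, 128) trained for 10 epochs on 1,000 balanced 64×64 patches
per contrast (about 5–6 minutes per model single-threaded); and 1,000-trial
randomized oracle comparisons for the deterministic primitives (linking,
jump equations, stop rule, Hausdorff, dwell deviations). Under these
conditions the oracle-mask configuration reconstructs all 10 catheters with
mean dwell deviation ≈ 0.07 mm (100% < 2 mm), and the end-to-end trained
configuration reaches held-out slice DSC ≈ 0.95 with zero missed catheters
— numbers the acceptance script recomputes on every run.

## Numerical notes and edge cases

- All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
  training, phantom generation and the pipeline are deterministic given
  their configuration.
- Binarization is strictly `> 0.5`; an exact 0.5 is background.
- `floor` in the stop rule is evaluated with a 1e-9 guard against
  float-representation jitter of exact multiples.
- Tied maxima inside max-pooling share the gradient equally; tied extrema
  in `refine_in_rectangle` resolve by distance then row-major order.
- Degenerate inputs fail loudly: constant volumes cannot be normalized,
  empty rectangles cannot be refined, empty paths cannot be resampled,
  zero detected catheters make the jump correction undefined (the caller
  falls back to carrying positions over), and geometries whose implanted
  length exceeds the imaged extent are rejected.

## Known limitations

- The tracker assumes roughly axial insertion; strongly oblique catheters
  violate the mm-per-slice mapping of the free-length rule (the
  `arc_length_stop` switch relaxes this but is off by default).
- Greedy one-to-one linking can mis-assign when two catheters cross within
  the linking radius on the same slice; the phantom's separation constraint
  reflects the physical implant, not an algorithmic guarantee.
- The absolute-value jump correction biases imputed positions when detected
  catheters move in opposing directions.
- Segmentation quality on real scanners/sequences is outside what the
  phantom can certify; retraining per sequence is expected.
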