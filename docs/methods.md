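# Methods

`woundmetry` measures chronic-wound size from ordinary photographs. The
clinical motivation is diabetic-foot ulcer follow-up, where the wound's
extent (area) and perimeter track healing and feed severity grading; the
package turns a photograph plus detector-supplied bounding boxes into
per-wound area (mm²) and perimeter (mm) expressed in the plane of a printed
fiducial marker of known physical size. Wound *detection* and
*classification* are deliberately out of scope: boxes and class labels
(blocked blood vessel 0, suture 1, ulceration 2, marker 3) arrive as input,
from any detector or from hand annotation.

## Pipeline model

For an image `X₀` with wound boxes `X_B1..X_Bm` and one marker box `X_M`:

1. **Histogram adjustment.** Each wound sub-image is per-channel
   histogram-equalized to the full 8-bit range. The mapping is monotone per
   channel, so color ordering — which the segmenter's mixture models rely
   on — is preserved while contrast is normalized across lighting
   conditions.

2. **Segmentation (GrabCut).** Inside each box the wound is separated from
   skin by iterated energy minimization over pixel labels α ∈ {fg, bg}:

       E(α, k, θ) = Σ_n min_k [ −log π_k − log N(z_n; μ_k, Σ_k) ]
                  + γ Σ_{(m,n)∈C, α_m≠α_n} dis(m,n)⁻¹ exp(−β‖z_m−z_n‖²)

   with K-component full-covariance RGB Gaussian mixtures per side,
   8-neighbor cliques C, `dis⁻¹` 1 for axis neighbors and 1/√2 for
   diagonals, and β = 1/(2⟨‖z_m−z_n‖²⟩) over all neighbor pairs (0 for a
   constant image). Iterations alternate (a) hard component assignment,
   (b) mixture re-estimation from assignments, (c) a global min-cut with the
   mixture data costs as terminal links. Each step is a block-coordinate
   descent move, so the per-iteration energy trace is non-increasing; the
   trace is part of the result and tested. Convergence is declared at
   relative energy change < 1e-4 or after 10 iterations.

   Pixels outside the initializing box are definite background. They are
   removed from the cut graph outright (pair weights incident to them fold
   into the neighbors' sink links), which enforces the constraint exactly
   without a large sentinel capacity. The min-cut runs on
   `scipy.sparse.csgraph.maximum_flow`, which needs integer capacities and
   overflows silently beyond int32; capacities are therefore shifted per
   pixel (the cheaper side to 0 — a labeling-independent constant), clipped
   at `max(1000, 100 γ)` (far above the largest possible pairwise saving of
   ~8 γ per pixel, so cut decisions are unchanged) and scaled adaptively so
   every capacity and the attainable cut value fit in 31 bits.

   Defaults K = 5, γ = 50, taken from the algorithm's standard published
   parameterization; covariances get `cov_reg·I` (1e-6) so flat-color
   regions stay nonsingular. Empty mixture components are re-seeded by
   splitting the heaviest component at its principal-axis median —
   deterministic, and skipped when that component has no color spread (a
   pointless split would jitter the energy). Initial assignments come from
   seeded per-side k-means, making whole runs bit-reproducible per seed.

3. **Contour extraction.** The outer boundary of each 8-connected
   foreground component is traced on the pixel *cracks* (pixel (r,c) spans
   the unit cell [c,c+1)×[r,r+1)), collinear runs merged, counter-clockwise
   orientation, components under 16 px² dropped. Crack polygons are exact
   for area (polygon area = pixel count) but overestimate the length of a
   smooth boundary by up to 4/π, so before measurement the pipeline
   resamples the boundary at 0.5 px and applies a circular Gaussian
   low-pass (σ = 1.5 px). On a rasterized disk of radius 20 this brings the
   perimeter from +27% error to within ~0.1%, while moving area by well
   under 1%.

4. **Marker registration.** ORB keypoints and binary descriptors are
   matched between the marker crop and the reference marker image
   (nearest-descriptor with ratio test 0.75, cross-check), pruned by RANSAC
   consensus on a projective model (3 px inlier threshold), requiring ≥ 8
   inliers; the detector backend is pluggable — the contract is the
   correspondence set, not the detector. The homography is then solved from
   the correspondences by the direct linear transform: rows
   `[x y 1 0 0 0 −x·xR −y·xR]` and `[0 0 0 x y 1 −x·yR −y·yR]` of a 2k×8
   system solved by least squares (exact at k = 4), the 3×3 matrix
   assembled with its bottom-right entry fixed to 1. Keypoint localization
   noise limits a correspondence-only fit to a few tenths of a degree of
   rotation, so the solution is polished photometrically
   (Levenberg-Marquardt on the 8 entries against the intensity difference
   between crop and warped reference), which on synthetic scenes reaches
   ~1e-4 degrees. The crop offset is pre-composed so the published
   transform maps full-image coordinates to reference coordinates.

5. **Quality gate.** The transform's rotation is defined as the angle of
   the orthogonal polar factor of its upper-left 2×2 block — stable under
   anisotropic scale and shear, equal to the plain angle for similarity
   transforms. Images rotated by strictly more than 15° are flagged
   unanalyzable and produce no measurements (an oblique shot makes the
   planar marker a poor proxy for the wound plane); 15.0° itself passes.

6. **Physical measurement.** Wound contours are transported through the
   homography into the reference frame and scaled by the reference's
   mm-per-pixel: area by the shoelace formula × (mm/px)², perimeter by edge
   length × mm/px. Polygon (not pixel-count) definitions mean transported
   contours need no re-rasterization. Every reported wound satisfies the
   isoperimetric inequality P² ≥ 4πA by construction.

**Contour accuracy metric.** Validation uses the percentile Hausdorff
distance: both contours are densified to ≤ 0.5-unit edge spacing, and the
statistic is the larger of the two directed p-th percentiles of
point-to-set distances (p = 100 gives the classic Hausdorff distance; the
90th-percentile variant used for acceptance is robust to thin spurs). The
symmetrized average Hausdorff distance is exposed alongside.

## Synthetic study conditions

No clinical images are distributed with this package, so every stage is
validated against a generator that emulates the *structure* of the study's
photographs: a skin-toned background (205,170,150) with Gaussian pixel
noise (default σ = 2), one or more wounds rendered as radially perturbed
ellipses `r(t) = 1 + a·sin(l·t + φ)` (irregularity a ∈ [0.04, 0.10], 3–6
lobes) with class-specific colors (dark purple for blocked vessels, pink
elongated shapes for sutures, raw red for ulcerations), and one square
128-px reference marker warped into the scene by a known similarity (+
optional perspective) transform at scale 0.7 in a 320×320 frame. The
marker reference texture is a smooth, aperiodic two-scale random field: a
checkerboard would die under the descriptor ratio test (all corners look
alike), and hard block corners quantize keypoint localization to the pixel
grid, which under fractional scale becomes spatially *correlated* error
that biases the fitted transform by ~1°.

Ground truth carries the wound polygons, masks, boxes, the exact
image-to-reference homography (its rotation equals the requested placement
rotation by construction, even with perspective), and physical
areas/perimeters derived from the transported polygons — self-consistent
with the package's own polygon arithmetic to 1e-9. The default reference
marker is declared 30 mm on a side (mm/px = 30/128); the physical side is
always a configuration input because a marker image alone carries no
scale.

What the generator does *not* model: real tissue texture, specular
highlights, shadows, blur, occlusion, or curved (non-planar) wound
surfaces. Passing tests therefore demonstrate the correctness of the
geometry, the optimization and the bookkeeping — not clinical segmentation
accuracy on real photographs, where appearance models and the planarity
assumption are the binding constraints.

Fixture defaults replicate the study's original class counts
(318 blocked-vessel, 64 suture, 345 ulceration = 727 images); augmentation
targets 900 records per class (treating the marker as a fourth annotation
class, 4 × 900 = 3,600 records, which is how the printed totals add up)
using horizontal/vertical flips, translations bounded at 10% of the side
and shears bounded at 8° — magnitudes are configurable since only the op
families are prescribed. Sheared boxes take the axis-aligned hull of the
transformed corners. Splitting defaults to 700 train / 200 test per class
by count; the alternative 3:1 ratio reading is available through the
`train_per_class` parameter. Because augmented records are near-duplicates
of their originals, the default split assigns whole augmentation lineages
to one side (no leakage, counts approximate); `by_lineage=False` reproduces
plain per-record splitting with exact counts — the variant that yields
exactly 200 test records per class.

## Numerical choices and edge cases

- Boxes are half-open `[xmin,xmax)×[ymin,ymax)` in 0-based x-right/y-down
  pixel coordinates.
- A box covering the whole sub-image leaves no background sample and is an
  error; an empty foreground after a cut returns an empty mask with a
  warning flag rather than failing the image.
- Mixture assignment ties break to the lowest component index.
- `rotation_angle` raises on a singular 2×2 block; homographies are
  normalized (and validated invertible) at construction.
- Contour transport raises if any vertex's homogeneous w falls to ~0
  (point at infinity).
- Reports are deterministic JSON (sorted keys, parameter hash, tool
  version); two runs with the same seed and inputs are byte-identical.

## Problem sizes used in validation

Acceptance-level checks run on 200 random homographies (8 correspondences
each), 50 random single-wound scenes for segmentation properties, 30
noiseless scenes (3 classes × 10) for end-to-end closure, a 7-point
rotation sweep for the quality gate, and the printed-scale dataset
bookkeeping (727 → 3,600 records) computed on annotation records without
rendering pixels.

## Known limitations

- Planarity: the marker calibrates the marker's plane; concave or steeply
  curved wound beds are foreshortened. The rotation gate bounds but does
  not remove this error.
- GrabCut is an appearance model; wounds whose color statistics overlap
  the surrounding skin (maceration, callus) will need parameter adjustment
  (γ, K, iterations are exposed) or manual correction, and segmentation on
  real clinical photographs is not validated here.
- One marker per image is required; multi-marker bundle adjustment and
  lens-distortion correction are out of scope.
- The photometric refinement assumes the scene marker and reference share
  the same modality (it minimizes raw intensity differences after
  grayscale conversion); strong non-monotone lighting changes would reduce
  its benefit, in which case the correspondence-only solution is still
  available (`refine=False`).
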