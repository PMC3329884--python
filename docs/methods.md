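# Methods

`featwarp` implements feature-based deformable image registration for 2-D
and 3-D scalar medical images.  The method has three stages: autodetection
of tissue feature points, association of points between the two images by
orientation-histogram (SIFT-style) descriptors with a ratio test and a
bidirectional consistency check, and interpolation of the matched control
points into a dense displacement field with thin-plate splines (TPS).  No
iterative optimisation is involved; the transformation follows in closed
form from the control points.

## Model and procedure

**Feature detection.**  Let I be the image and ∇I its gradient, computed
by central differences per axis, (1/2)(I_{i+1,j,k} − I_{i−1,j,k}) etc., in
image units per voxel step, with replicated-edge neighbours at the
boundary.  A voxel is a candidate feature when its intensity lies in a
tissue window (CT numbers: bone > 100, soft tissue such as pancreas
0–100; the default window (0, 3000) spans all tissue while excluding the
air–skin transition) and its saliency — Σ‖∇I‖² over the 3×3×3
neighbourhood — is positive.  Candidates undergo greedy non-maximum
suppression within a physical radius (default 3 mm), visited strongest
first with lexicographic tie-breaks, and are then thresholded at the 90th
percentile of in-window saliency (or an absolute threshold), sorted, and
capped at 10 000 points.  Suppression runs before thresholding so that
raising the threshold can only remove points.  The detector is
deliberately simple; the descriptor matcher carries the discriminative
burden.

**Descriptor.**  The 8×8×8-voxel window about a point (offsets −4…+3) is
split into eight 4×4×4 octants.  For each octant and each coordinate plane
(xy, yz, zx), the in-plane projection of every voxel gradient is binned by
its in-plane angle into eight 45° bins over [0°, 360°), accumulating the
in-plane magnitude: 8 × 3 × 8 = 192 components.  Single-slice images use
the planar analogue (8×8 window, 4 quadrants, xy plane only: 32
components), and the two modes are never compared.  There is no rotation
invariance, Gaussian weighting, or normalisation by default: descriptors
are compared raw, by the squared-difference score
S = Σ_α |a_α − b_α|².

**Matching.**  For each template point, S is computed against every
detected target point (optionally within a physical search radius); the
two smallest scores S₁ ≤ S₂ define the ratio κ = S₁/S₂, and the
association is kept only if κ < 0.5.  Degenerate cases are fixed for
determinism: κ := 0 when S₁ = 0, and ties break toward the smaller
lexicographic target voxel index.  The bidirectional pass then re-matches
every associated target point back into the template set under the same
rule and deletes pairs whose reverse match is not the original template
point, leaving mutual best matches.

**TPS interpolation.**  With n control points p_i, each output coordinate
is f(x) = a₁ + a·x + Σ w_i U(|p_i − x|) with the kernel
U(r) = r² log r² (limit 0 at r = 0), applied in 3-D exactly as in 2-D
(the true 3-D biharmonic kernel U(r) = |r| is available as an option).
Coefficients solve the dense system L (W | a)ᵀ = Y with
L = [[K, P], [Pᵀ, 0]], K_ij = U(r_ij) (zero diagonal), P = [1 | p_i]; the
Pᵀ block enforces Σw = 0 and Σw·p = 0, giving exact interpolation at the
control points and exact reproduction of affine correspondences.  The fit
uses source = target landmarks and destination = template landmarks, so
the dense field d(x) = f(x) − x on the target grid is a target→template
(backward-warping) field and resampling the template through it leaves no
holes.  Optional ridge weight λ on K's diagonal turns the interpolating
spline into an approximating one (default λ = 0).  Duplicate source
points (< 1e-6 mm apart) are merged by averaging destinations.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `intensity_window` | (0, 3000) | tissue selection, image units |
| `saliency_quantile` | 0.90 | detection threshold as in-window quantile |
| `nms_radius` | 3 mm | minimum physical separation of features |
| `max_points` | 10 000 | detector cap per image |
| `kappa_threshold` | 0.5 | ratio-test acceptance bound |
| `search_radius` | unlimited | optional candidate restriction (mm) |
| `tps_ridge` | 0 | exact interpolation; > 0 approximates |

All geometry is in physical millimetres: voxel v maps to
origin + v·spacing, anisotropic spacing is respected everywhere except in
the descriptor itself, whose gradients are per voxel step (so strongly
anisotropic voxels make the descriptor anisotropic — a documented
limitation).

## Synthetic phantoms

The package ships a digital phantom generator so the whole pipeline is
testable end-to-end with exact ground truth.  A phantom is a CT-like
scene: an air background (−1000), a soft-tissue body (≈40) bounded by an
ellipse/ellipsoid whose radius carries a small smooth random perturbation
(default ±5%), multi-scale Gaussian-blob texture (σ ∈ [0.5, 1.5] ×
`texture_scale`, amplitude s.d. 250), a ring of bright bone-like nodules
near the periphery (the rib cross-sections an axial slice always shows;
contrast +700), and optional spherical markers of varying radius (5–10
mm) and contrast (+600 to +1400) — rigid inserts of known position, as in
physical deformable phantoms.  The irregular contour, multi-scale
texture, rib ring and heterogeneous markers are not decoration: real
anatomy is locally distinctive, and a perfectly smooth ellipse with
uniform texture or identical spheres is *more* ambiguous than any
clinical image, which starves the ratio test of unambiguous matches.

Deformations with exact ground truth:

* **Harmonic warp** x′(x, y) = (1 + b cos m q)·x, q = atan2(y, x) about
  the body centre; b sets the magnitude and m the angular complexity, and
  only x moves.  The target image is produced by backward sampling
  through the numerically inverted map (vectorised Newton with a
  bracketed-root fallback, tolerance 1e-6 mm) with cubic-spline
  resampling; the ground-truth field is stored on the target grid in the
  same target→template convention as registration output, so evaluation
  is a direct subtraction.  Markers move analytically.
* **Gaussian-lobe field** (3-D): d(x) = Σ a_l exp(−|x − c_l|²/2σ²),
  normalised so the sampled peak |d| matches a requested value; inverted
  per voxel by fixed-point iteration.  A sampled finite-difference bound
  on ‖∇d‖ rejects non-invertible requests before resampling.
* **Rigid translation**, for exact-recovery checks.

## Standard experiments

Two experiment drivers (also used by `scripts/acceptance.py`) fix the
package's reference problem sizes:

* **2-D harmonic study** — 170×170 slice at 2.0 mm (34 cm field of view;
  body ≈ 27×30 cm), harmonic warp with b = 0.12, m = 1 about the body
  centre, giving ≈16 mm peak displacement.  b·a_x sets the peak (a_x the
  body x semi-axis); the local strain grows roughly as b(1 + m/2), and
  beyond m ≈ 2 it exceeds what a descriptor with no rotation invariance
  tolerates, so the default keeps m low and reaches the target magnitude
  through b.  Errors are the per-pixel magnitudes of (estimated − true)
  displacement over in-body pixels; the body mask is the template mask
  backward-warped into the target frame.  Evaluation is body-masked
  because no control points exist outside the body and TPS extrapolation
  there is meaningless.
* **3-D marker study** — 128³ at 1.5 mm (19 cm field of view), 24 markers,
  6-lobe Gaussian deformation with σ = 45 mm normalised to 18 mm peak
  (respiratory-scale motion).  Each marker's residual is the distance
  between its true template position and the TPS-mapped position of its
  deformed location — a target-registration-error statistic — summarised
  as the fraction below 2 mm.
* **Translation study** — 64³ phantom against a copy shifted by an integer
  number of voxels; surviving matches must recover the shift exactly.

What these phantoms do **not** emulate: CT noise and artefacts beyond
smooth texture, intensity changes between phases (contrast, density
change under compression), sliding discontinuities at organ interfaces,
and anatomy appearing/disappearing between images.  Passing results show
the pipeline recovers smooth invertible deformations of textured scenes
at clinically relevant magnitudes; they do not certify performance on
noisy or discontinuous clinical motion.

## Numerical choices and edge cases

* Descriptor bins are half-open ([45°b, 45°(b+1))); an angle exactly on an
  edge goes up.  Zero-magnitude in-plane projections contribute nothing.
* The even descriptor window is anchored at offsets [−4, +3] about the
  centre voxel; quadrant order is the bit code (x≥0)<<2 | (y≥0)<<1 |
  (z≥0).
* Matching distances use exhaustive `cdist` in float64, chunked over
  template rows; no approximate indexing, so outputs equal the exhaustive
  search by construction.
* The TPS system is solved densely (LAPACK); degenerate geometry
  (collinear/coplanar sources) is rejected up front by a rank check.
* Warping uses linear interpolation with a configurable fill (default:
  template minimum); sampling coordinates within 1e-6 voxel of the grid
  edge are snapped onto it so that a numerically-zero displacement
  reproduces the input exactly.
* q at the deformation centre (x = y = 0) is defined as 0; the harmonic
  map is the identity there regardless.
* All randomness flows through explicit integer seeds; repeated runs are
  bit-identical, and the parallel-free reference path is the semantic
  contract.

## Known limitations

* No rotation invariance or descriptor normalisation means large local
  rotations/strains (harmonic m ≥ 3 at b = 0.12, i.e. ≳35% strain) break
  descriptor matching near strong edges; mismatches that survive both
  filters are interpolated exactly by the TPS and corrupt the field
  locally.  A ridge term or a search radius mitigates but is off by
  default.
* Matching is voxel-quantised: expected control-point error is a fraction
  of a voxel, so accuracy degrades with coarse spacing.
* Dense-search association (every target voxel as a candidate) is not
  implemented; candidates are detected target features only.
* Direction cosines other than identity are rejected; no DICOM series
  assembly or 4-D containers.
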