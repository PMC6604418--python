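# Methods

## Geometry and conventions

A rigid transform `T` maps coordinates as `x_dst = R x_src + t`, with
translations in millimetres. This is the only convention under which the
virtual-camera poses take the form `t_2v = −R_12⁻¹ t_12 − b`: the camera-2
centre expressed in frame 1 is then `−R_12⁻¹ t_12`, and the barycenter `b`
is the mean of `0`, `−R_12⁻¹ t_12` and `−R_13⁻¹ t_13`. The convention is
pinned by tests (composition consistency `T_1to2 ∘ T_2toV = T_1toV`).

Pixels are 0-based with `(0, 0)` the centre of the top-left pixel; `u` is
the column, `v` the row. The principal point of the synthetic cameras sits
at the geometric centre `((w−1)/2, (h−1)/2)`.

Lens distortion is the two-coefficient radial model
`x_d = x (1 + k1 r² + k2 r⁴)` on normalized coordinates; tangential terms
are not modelled. Plane-induced homographies are valid only for pinhole
images, so images (or corner coordinates) are undistorted *before* any
homography is applied. The inverse of the radial model reduces to a scalar
equation in the radius, solved by damped Newton iteration (tolerance 1e−10,
cap 50 iterations); the model is invertible only while
`1 + 3 k1 r² + 5 k2 r⁴ > 0`, which holds across the field of view for the
small coefficients typical of these lenses, and the solver raises rather
than returning a wrong branch when it does not.

Calibration *estimation* is out of scope: the rig consumes the outputs of a
standard plane-based calibration through a YAML file (17-significant-digit
decimal serialization, hence bit-exact round trips), validating rotation
orthonormality (tolerance 1e−6 on file input, 1e−9 internally) and the
millimetre units tag.

## Virtual camera

The virtual camera sits at the barycenter of the three optical centres and
is oriented as camera 1. Its intrinsics come in two modes:

- **fixed** — `K_v` = camera-1 intrinsics (distortion zeroed), canvas
  400 × 400. Used by the quantitative evaluation so that "percent of the
  warped image side" has an unambiguous 400 px denominator.
- **auto** — keep camera-1 focal lengths, grow the canvas to the bounding
  box of the warped corners of all three source images (plus a margin) and
  recentre the principal point. This realizes a "wider field of view that
  encompasses all three views" with the least added assumption.

The homography plane is taken parallel to the virtual image plane (normal
`(0,0,1)` in the virtual/camera-1 orientation), because the true operative
plane orientation cannot be known in advance.

### Distance conventions

The navigation stitcher specifies the plane distance `d₁` from **camera
1** (40 mm default, the typical valve-release distance). The evaluation
measures board distances and the plane distance from the **virtual
camera** along its optical axis. In the converged default rig camera 1 is
≈ 2.7 mm off the virtual principal plane, so the two origins differ; the
evaluation's convention is the one under which the misalignment minimum
falls exactly at the nominal plane distance. `plane_in_frame` converts
between all frames (`n_i = R n₁`, `d_i = d₁ + n_iᵀ t`).

## Stitching

Warping is inverse mapping: each canvas pixel is pulled back through
`H⁻¹` and sampled with bilinear (default) or nearest interpolation;
a pixel is valid when its homogeneous scale is positive (λ ≤ 1e−12 flags
behind-camera/at-infinity content rather than wrapping it into the canvas)
and the source coordinate is in bounds. Homographies are stored normalized
to unit Frobenius norm with `h₃₃ > 0` where meaningful; the projective
scale λ makes the normalization semantically irrelevant but numerically
tidy.

Two blend modes reproduce the presentation variants evaluated with
surgeons:

- **hard_lines** — every covered pixel comes from exactly one layer: the
  one whose pre-warp source sample lies closest to that camera's principal
  point ("most central view wins", ties to the lower camera index), with
  1 px seam lines drawn where two covered ownership regions meet. The
  partition rule is a design choice; it approximates per-camera sectors.
- **feathered** — convex combination with per-layer weights
  `min(dist_to_mask_edge, w_f)/w_f` (distance transform, default
  `w_f = 40 px`), normalized to a partition of unity wherever any layer
  covers. This yields the "blurred borders" transition.

The three-views comparison mode rotates images 2 and 3 in-plane by the Z
angle of the intrinsic Z-Y-X Euler decomposition of `R_12⁻¹` / `R_13⁻¹`
about their centres (canvas kept at source size), making all horizons
parallel to camera 1's.

## Synthetic rig and chessboard simulator

The generator reproduces the instrument geometry: three identical
400 × 400 px cameras, 120° diagonal field of view (`f = (diag/2)/tan 60° ≈
163.3 px`), zero distortion by default, centres 120° apart on a
21 mm-diameter circle (camera 1 at the top of the cross-section), all in
one cross-sectional plane. The tilt angle of the "radially oriented"
cameras is not part of the published geometry; the default aims each
optical axis at the instrument-axis point 40 mm ahead — convergence at the
nominal working distance — and a `parallel` mode keeps the axes parallel
for closed-form cross-checks. In-plane camera orientation uses the minimal
rotation from the instrument axis to the viewing direction (no roll).

Chessboard targets default to 7 × 8 inner corners with 3 mm squares (a
board of 8 × 9 squares; at the working distance each camera then sees at
most 56 corners, consistent with the instrument's documented 32–56 range).
Boards are rasterized by exact projective ray casting with supersampled
antialiasing (factor 4 by default); inner corners are additionally
projected analytically, distortion included, so all quantitative results
rest on exact geometry, never on the raster or on corner detection. A
gradient-moment subpixel detector in the test suite audits that the raster
and the analytic ground truth agree to better than 0.1 px.

`perturb_calibration` emulates residual calibration error (seeded random
axis/angle rotation noise, translation noise, fractional intrinsics
jitter); the evaluation applies it to the calibration used for the
homographies while ground truth keeps the true geometry, which is exactly
how calibration error enters a real system.

## Misalignment evaluation

For each camera pair and every corner visible in both views, the
(undistorted) corner pixels are mapped through the two stitching
homographies and the Euclidean distance between the mapped canvas
positions is recorded. Reported are the per-pair mean and *population*
standard deviation (the divisor-n choice is pinned for reproducibility),
in px and as a percentage of the canvas side (400 px in fixed mode), plus
a pooled row formed as the unweighted mean of the three pair means (and of
the pair stds). The depth sweep places the board parallel to the virtual
image plane at 30–50 mm in 2.5 mm steps while the homographies stay fixed
at the 40 mm plane.

For parallel-axis rigs the expected pair misalignment has the exact closed
form `f_v |t⊥| |1/z − 1/d|` (baseline component perpendicular to the
axis); the test suite uses it as an independent oracle against the full
pipeline, and a first-order version of the same formula cross-checks the
converged default rig.

With exact calibration the on-plane error is zero to machine precision;
the published physical measurement at the plane (≈ 0.46 % of the image
side) additionally contains calibration residuals, so the exact-geometry
value is a strict lower bound. Off-plane, the geometric parallax dominates
and the synthetic sweep lands close to the physical measurements.

## What the synthetic study does and does not show

The simulator captures the rig geometry, projective image formation,
radial distortion and (optionally) calibration noise. It does not model
photometric effects (LED illumination falloff, specularities, blur,
sensor noise), fisheye-specific distortion beyond two radial terms,
synchronization jitter, or deformable anatomy; passing tests therefore
validate the geometric stitching engine and its error model, not
photometric robustness on real endoscopic video. Timing figures from the
`benchmark` subcommand are hardware- and implementation-dependent and are
reported for information only.

## Problem sizes

Default test and evaluation sizes — 400 × 400 px images, 56-corner boards,
nine sweep distances, 100 randomized configurations for the
homography-vs-DLT equivalence, 20 seeds × 3 magnitudes for the noise
monotonicity study — keep the whole suite at well under a minute while
exercising every code path; they are the package's reference
configuration, not a statistical compromise (the evaluation is
deterministic given the geometry).
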