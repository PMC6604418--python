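# tricamstitch

Real-time-oriented image stitching for a three-eyed endoscopic vision
system, aimed at minimally invasive aortic valve surgery. Three miniature
cameras sit 120° apart on a 21 mm-diameter circle at the tip of a flexible
manipulator, looking down the aorta toward the annulus plane. Because the
cameras are decentralized and non-parallel, the raw views are disorienting;
stitching them into a single central view restores spatial awareness during
navigation and valve deployment.

The method needs no feature detection or homography estimation. With the
rig calibration known, the map from each camera image to a **virtual
camera** at the barycenter of the three optical centres (oriented as
reference camera 1) is a closed-form *plane-induced homography*. For two
cameras related by `x_j = R x_i + t` and a working plane with unit normal
`n` and distance `d` in camera *i* coordinates,

    H_ij = K_j (R + t nᵀ / d) K_i⁻¹ ,

applied in homogeneous pixel coordinates (`λ x_j = H_ij x_i`). The three
stitching maps `H_1v, H_2v, H_3v` use the virtual poses

    R_1v = I,        t_1v = −b
    R_2v = R_12⁻¹,   t_2v = −R_12⁻¹ t_12 − b
    R_3v = R_13⁻¹,   t_3v = −R_13⁻¹ t_13 − b

with `b` the barycenter in camera-1 coordinates. Content **on** the plane
(set 40 mm ahead, the typical valve-release distance) stitches exactly;
content at depth `z` off the plane shows parallax misalignment that grows
like `f · |t⊥| · |1/z − 1/d|`.

The package provides:

- `camera_model` — intrinsics with a two-coefficient radial distortion
  model, rigid transforms, projection, and a YAML calibration file format;
- `rig_geometry` — barycenter, virtual-camera poses and intrinsics, plane
  re-expression between camera frames;
- `homography` — the closed-form plane-induced maps and their application;
- `stitcher` — inverse warping onto the virtual canvas with hard-seam or
  feathered ("blurred borders") blending, plus the horizon-aligned
  three-views presentation mode;
- `synthetic_rig` — a simulator of the rig geometry and chessboard targets
  with exact analytic corner ground truth;
- `evaluation` / `cli` — the quantitative chessboard misalignment protocol,
  depth sweep, CSV/plot reports, and the `tricamstitch` command line.

## Worked example

Run the chessboard depth sweep on the default synthetic rig (exact
calibration, homography plane fixed at 40 mm from the virtual camera,
virtual intrinsics pinned to camera 1 on a 400 × 400 canvas, 7 × 8-corner
board with 3 mm squares):

```
$ tricamstitch sweep --out sweep/
 distance_mm     mean_pct      std_pct  n
        30.0 6.123420e+00 1.822111e-01 56
        32.5 4.235874e+00 1.167197e-01 56
        35.0 2.620509e+00 6.723356e-02 56
        37.5 1.222257e+00 2.933762e-02 56
        40.0 1.692213e-14 6.834803e-15 56
        42.5 1.077594e+00 2.291111e-02 56
        45.0 2.034822e+00 4.092566e-02 56
        47.5 2.890820e+00 5.516159e-02 56
        50.0 3.660865e+00 6.644887e-02 56
```

Each row is the pooled mean misalignment between pairs of warped views, as
a percentage of the 400 px image side, for the board at that distance from
the virtual camera. At the homography plane (40 mm) the error is zero to
machine precision — the defining property of plane-induced stitching with
exact calibration; 10 mm nearer (30 mm) the parallax reaches ≈ 6.1 % of the
image side, and it grows monotonically with |1/z − 1/d| on both sides. The
full per-pair table lands in `sweep/misalignment.csv` and an error-trend
plot (error bars ± 2 std) in `sweep/error_trend.png`.

Other subcommands: `tricamstitch simulate` renders the synthetic rig's
three chessboard views with calibration and ground-truth corners;
`tricamstitch stitch img1 img2 img3 --calibration calib.yaml` produces the
stitched view (`--blend hard|feathered`, `--three-views` for the
horizon-aligned side-by-side mode); `tricamstitch benchmark` reports the
per-frame stitch time (informational — e.g. `98.41 +/- 12.09 ms over 10
frames` on one modest CPU core with the pure-Python/NumPy pipeline).

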