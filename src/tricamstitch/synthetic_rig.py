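"""Synthetic three-camera rig and chessboard scenes with exact ground truth.

The default rig emulates the miniature endoscopic setup the package targets:
three 400x400 px cameras with a 120-degree diagonal field of view, centred
120 degrees apart on a 21 mm-diameter circle at the tip of the instrument,
optical axes converging on the instrument axis at the 40 mm working distance.
Chessboard targets are rendered by exact projective ray casting with
supersampled antialiasing, and every inner corner is also projected
analytically (distortion included), so evaluation never depends on corner
detection or rasterization fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .camera_model import (
    BehindCameraError,
    CameraIntrinsics,
    RigidTransform,
    TriRig,
    compose,
    invert,
    project_point,
    undistort_normalized,
)

__all__ = [
    "RigSpec",
    "ChessboardSpec",
    "GroundTruth",
    "default_intrinsics",
    "make_default_rig",
    "board_corners_3d",
    "project_board",
    "render_chessboard",
    "perturb_calibration",
]


def default_intrinsics(width: int = 400, height: int = 400,
                       diagonal_fov_deg: float = 120.0) -> CameraIntrinsics:
    """Distortion-free intrinsics from image size and diagonal field of view.

    f = (diagonal/2) / tan(fov/2); for 400x400 at 120 degrees this gives
    f ~= 163.3 px. Principal point at the geometric image centre.
    """
    half_diag = 0.5 * float(np.hypot(width, height))
    f = half_diag / np.tan(np.deg2rad(diagonal_fov_deg) / 2.0)
    return CameraIntrinsics(
        fx=f, fy=f, cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
        width=width, height=height,
    )


@dataclass(frozen=True)
class RigSpec:
    """Geometry of the synthetic rig.

    Camera 1 sits at the top of the circle (90 degrees in the cross-section);
    the others follow at -120-degree steps. ``tilt_mode='converge'`` aims each
    optical axis at the point on the instrument axis ``converge_mm`` ahead;
    ``'parallel'`` keeps all axes parallel to the instrument axis (useful for
    closed-form cross-checks). Optional pose jitter (applied with the seed)
    roughens the ideal geometry.
    """

    circle_diameter_mm: float = 21.0
    angles_deg: tuple[float, float, float] = (90.0, -30.0, 210.0)
    tilt_mode: str = "converge"
    converge_mm: float = 40.0
    camera: CameraIntrinsics = field(default_factory=default_intrinsics)
    jitter_rot_deg: float = 0.0
    jitter_trans_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.circle_diameter_mm < 0:
            raise ValueError("circle diameter must be non-negative")
        if len(set(self.angles_deg)) != 3:
            raise ValueError("camera angular positions must be distinct")
        if self.tilt_mode not in ("parallel", "converge"):
            raise ValueError(f"unknown tilt_mode {self.tilt_mode!r}")
        if self.tilt_mode == "converge" and self.converge_mm <= 0:
            raise ValueError("convergence distance must be positive")


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation (Rodrigues) taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-15:
        if c > 0:
            return np.eye(3)
        raise ValueError("180-degree alignment is ambiguous")
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def make_default_rig(spec: RigSpec | None = None, seed: int | None = None) -> TriRig:
    """Build the synthetic rig; deterministic unless the spec requests jitter.

    Camera frames use the usual convention: z along the viewing direction,
    x right, y down in the image. In-plane orientation is fixed by the
    minimal rotation from the instrument axis to the viewing direction
    (cameras do not roll about their own axes).
    """
    spec = spec or RigSpec()
    radius = spec.circle_diameter_mm / 2.0
    target = np.array([0.0, 0.0, spec.converge_mm])

    centers, rotations = [], []
    for ang in spec.angles_deg:
        th = np.deg2rad(ang)
        c = np.array([radius * np.cos(th), radius * np.sin(th), 0.0])
        if spec.tilt_mode == "parallel" or radius == 0.0:
            direction = np.array([0.0, 0.0, 1.0])
        else:
            direction = target - c
            direction = direction / np.linalg.norm(direction)
        Q = _rotation_aligning(np.array([0.0, 0.0, 1.0]), direction)
        centers.append(c)
        rotations.append(Q.T)  # rows are camera axes in rig coordinates

    def rel(i: int) -> RigidTransform:
        # x_i = A_i (x_rig - c_i)  =>  x_i = A_i A_1^T x_1 + A_i (c_1 - c_i)
        A1, Ai = rotations[0], rotations[i]
        return RigidTransform(Ai @ A1.T, Ai @ (centers[0] - centers[i]))

    rig = TriRig(
        cam1=spec.camera, cam2=spec.camera, cam3=spec.camera,
        T_1to2=rel(1), T_1to3=rel(2),
    )
    if spec.jitter_rot_deg > 0 or spec.jitter_trans_mm > 0:
        rig = perturb_calibration(
            rig, spec.jitter_rot_deg, spec.jitter_trans_mm, 0.0,
            seed=0 if seed is None else seed,
        )
    return rig


# ---------------------------------------------------------------------------
# chessboard target
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChessboardSpec:
    """A planar chessboard target, placed rigidly in the camera-1 frame.

    ``inner_rows x inner_cols`` is the interior corner grid (the default
    7x8 = 56 corners corresponds to a board of 8x9 squares of 3 mm side).
    Board coordinates: x along columns, y along rows, z = 0 on the board
    plane, origin at the centre of the corner grid. ``pose`` maps board
    coordinates into the camera-1 frame.
    """

    inner_rows: int = 7
    inner_cols: int = 8
    square_mm: float = 3.0
    pose: RigidTransform = field(
        default_factory=lambda: RigidTransform(np.eye(3), np.array([0.0, 0.0, 40.0]))
    )

    def __post_init__(self) -> None:
        if self.inner_rows < 2 or self.inner_cols < 2:
            raise ValueError("corner grid must be at least 2x2")
        if self.square_mm <= 0:
            raise ValueError("square side must be positive")

    @property
    def n_corners(self) -> int:
        return self.inner_rows * self.inner_cols


def board_corners_3d(board: ChessboardSpec) -> np.ndarray:
    """Inner-corner coordinates in the board frame, row-major, shape (N, 3)."""
    s = board.square_mm
    xs = (np.arange(board.inner_cols) - (board.inner_cols - 1) / 2.0) * s
    ys = (np.arange(board.inner_rows) - (board.inner_rows - 1) / 2.0) * s
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])


@dataclass(frozen=True)
class GroundTruth:
    """Analytic corner projections for each camera of the rig.

    ``pixels[i]`` is (N, 2) with NaN rows for corners behind camera i+1;
    ``visible[i]`` flags corners projecting inside camera i+1's bounds with
    positive depth. ``corners_frame1`` are the 3D corner positions (mm) in
    the camera-1 frame.
    """

    pixels: tuple[np.ndarray, np.ndarray, np.ndarray]
    visible: tuple[np.ndarray, np.ndarray, np.ndarray]
    corners_frame1: np.ndarray
    board: ChessboardSpec
    rig: TriRig


def project_board(rig: TriRig, board: ChessboardSpec) -> GroundTruth:
    """Project every inner corner into each camera (distortion applied)."""
    corners1 = board.pose.apply(board_corners_3d(board))
    pixels, visible = [], []
    for i in (1, 2, 3):
        cam = rig.cameras[i - 1]
        pts = rig.transform_from_cam1(i).apply(corners1)
        z = pts[:, 2]
        px = np.full((pts.shape[0], 2), np.nan)
        front = z > 0
        if np.any(front):
            px[front] = project_point(pts[front], cam, apply_distortion=True)
        vis = front & np.all(np.isfinite(px), axis=1)
        vis &= (
            (px[:, 0] >= 0) & (px[:, 0] <= cam.width - 1)
            & (px[:, 1] >= 0) & (px[:, 1] <= cam.height - 1)
        )
        pixels.append(px)
        visible.append(vis)
    return GroundTruth(
        pixels=tuple(pixels), visible=tuple(visible),
        corners_frame1=corners1, board=board, rig=rig,
    )


def _render_one(cam: CameraIntrinsics, T_board_to_cam: RigidTransform,
                board: ChessboardSpec, supersample: int,
                background: float) -> np.ndarray:
    w, h = cam.size
    F = int(supersample)
    # Subpixel sample centres covering each pixel's footprint.
    sub = (np.arange(w * F) + 0.5) / F - 0.5
    subv = (np.arange(h * F) + 0.5) / F - 0.5
    uu, vv = np.meshgrid(sub, subv)
    xn = np.stack(
        [(uu - cam.cx) / cam.fx - cam.skew * (vv - cam.cy) / (cam.fx * cam.fy),
         (vv - cam.cy) / cam.fy], axis=-1
    ).reshape(-1, 2)
    if cam.k1 != 0.0 or cam.k2 != 0.0:
        xn = undistort_normalized(xn, cam.k1, cam.k2, tol=1e-9)
    rays = np.column_stack([xn, np.ones(len(xn))])

    T_cam_to_board = invert(T_board_to_cam)
    # Board plane in camera coordinates: n . x = n . p0.
    n = T_board_to_cam.R @ np.array([0.0, 0.0, 1.0])
    p0 = T_board_to_cam.t
    denom = rays @ n
    offset = float(n @ p0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstar = offset / denom
    hit = np.isfinite(tstar) & (tstar > 0)
    img = np.full(rays.shape[0], background)
    if np.any(hit):
        pts_cam = rays[hit] * tstar[hit, None]
        pts_board = T_cam_to_board.apply(pts_cam)
        s = board.square_mm
        half_w = (board.inner_cols + 1) / 2.0 * s
        half_h = (board.inner_rows + 1) / 2.0 * s
        bx, by = pts_board[:, 0], pts_board[:, 1]
        on_board = (np.abs(bx) <= half_w) & (np.abs(by) <= half_h)
        # Square edges sit at half-integer multiples of s (corner grid centred).
        parity = (
            np.floor((bx + half_w) / s) + np.floor((by + half_h) / s)
        ).astype(np.int64) % 2
        shade = np.where(parity == 0, 0.0, 255.0)
        img[hit] = np.where(on_board, shade, background)
    img = img.reshape(h * F, w * F)
    return img.reshape(h, F, w, F).mean(axis=(1, 3))


def render_chessboard(
    rig: TriRig,
    board: ChessboardSpec,
    supersample: int = 4,
    background: float = 128.0,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Render the board into all three cameras and return analytic ground truth.

    Images are float arrays in [0, 255]; rasterization uses exact projective
    ray casting with ``supersample``^2 samples per pixel. Raises if the board
    centre is behind any camera.
    """
    gt = project_board(rig, board)
    center1 = board.pose.apply(np.zeros(3))
    images = []
    for i in (1, 2, 3):
        T_1toi = rig.transform_from_cam1(i)
        if T_1toi.apply(center1)[2] <= 0:
            raise BehindCameraError(f"board centre is behind camera {i}")
        T_b_to_cam = compose(board.pose, T_1toi)
        images.append(
            _render_one(rig.cameras[i - 1], T_b_to_cam, board, supersample, background)
        )
    return images, gt


# ---------------------------------------------------------------------------
# calibration perturbation
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator, angle_std_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, angle_std_deg))
    vx = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * vx + (1 - np.cos(angle)) * vx @ vx


def perturb_calibration(
    rig: TriRig,
    rot_noise_deg: float = 0.0,
    trans_noise_mm: float = 0.0,
    intrinsics_noise_frac: float = 0.0,
    seed: int = 0,
) -> TriRig:
    """Emulate residual calibration error with small seeded random offsets.

    Extrinsic rotations are pre-multiplied by a random rotation (axis uniform
    on the sphere, angle gaussian with the given std); translations get
    per-component gaussian offsets; fx, fy, cx, cy get fractional gaussian
    jitter. Zero noise returns the rig unchanged.
    """
    if min(rot_noise_deg, trans_noise_mm, intrinsics_noise_frac) < 0:
        raise ValueError("noise magnitudes must be non-negative")
    if rot_noise_deg == trans_noise_mm == intrinsics_noise_frac == 0:
        return rig
    rng = np.random.default_rng(seed)

    def jit_T(T: RigidTransform) -> RigidTransform:
        dR = _random_rotation(rng, rot_noise_deg) if rot_noise_deg > 0 else np.eye(3)
        dt = rng.normal(0.0, trans_noise_mm, 3) if trans_noise_mm > 0 else 0.0
        return RigidTransform(dR @ T.R, T.t + dt)

    def jit_cam(cam: CameraIntrinsics) -> CameraIntrinsics:
        if intrinsics_noise_frac == 0:
            return cam
        g = 1.0 + rng.normal(0.0, intrinsics_noise_frac, 4)
        return replace(cam, fx=cam.fx * g[0], fy=cam.fy * g[1],
                       cx=cam.cx * g[2], cy=cam.cy * g[3])

    return TriRig(
        cam1=jit_cam(rig.cam1), cam2=jit_cam(rig.cam2), cam3=jit_cam(rig.cam3),
        T_1to2=jit_T(rig.T_1to2), T_1to3=jit_T(rig.T_1to3),
    )
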