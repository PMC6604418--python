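"""Virtual-camera construction and plane bookkeeping.

The stitched view is rendered from a *virtual camera* placed at the barycenter
of the three optical centres and oriented as camera 1 (the reference). Its
pose relative to each real camera follows directly from the rig extrinsics:

    R_1v = I,        t_1v = -b
    R_2v = R_12^-1,  t_2v = -R_12^-1 t_12 - b
    R_3v = R_13^-1,  t_3v = -R_13^-1 t_13 - b

with ``b`` the barycenter in camera-1 coordinates. The homography plane is
stored as a :class:`PlaneSpec` (unit normal + signed distance) in a named
frame and re-expressed between frames as needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera_model import (
    BehindCameraError,
    CameraIntrinsics,
    RigidTransform,
    TriRig,
    identity_transform,
    invert,
)

__all__ = [
    "PlaneSpec",
    "VirtualCamera",
    "compute_barycenter",
    "virtual_poses",
    "plane_in_frame",
    "plane_from_virtual",
    "fit_virtual_intrinsics",
]

Frame = str | int  # 1, 2, 3 or "V"


@dataclass(frozen=True)
class PlaneSpec:
    """A world plane ``n . x = d`` expressed in one camera's frame.

    ``d`` is the signed distance (mm) from that camera's origin; the
    homographies require ``d > 0`` (plane in front of the camera).
    """

    frame: Frame
    n: np.ndarray
    d: float

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"plane normal must be unit length, |n| = {norm}")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "d", float(self.d))


@dataclass(frozen=True)
class VirtualCamera:
    """The barycentric virtual viewpoint: distortion-free intrinsics + poses."""

    K_v: CameraIntrinsics
    T_1toV: RigidTransform
    T_2toV: RigidTransform
    T_3toV: RigidTransform

    def __post_init__(self) -> None:
        if self.K_v.k1 != 0.0 or self.K_v.k2 != 0.0:
            raise ValueError("virtual camera must be distortion-free")
        if not np.allclose(self.T_1toV.R, np.eye(3), atol=1e-9):
            raise ValueError("virtual camera must be oriented as camera 1")

    @property
    def canvas_size(self) -> tuple[int, int]:
        """(width, height) of the stitching canvas in px."""
        return self.K_v.size

    def pose_from_camera(self, i: int) -> RigidTransform:
        return (self.T_1toV, self.T_2toV, self.T_3toV)[i - 1]


def compute_barycenter(rig: TriRig) -> np.ndarray:
    """Barycenter of the three optical centres, in camera-1 coordinates (mm)."""
    centers = [rig.camera_center_in_frame1(i) for i in (1, 2, 3)]
    return np.mean(centers, axis=0)


def virtual_poses(rig: TriRig) -> tuple[RigidTransform, RigidTransform, RigidTransform]:
    """Poses T_itoV mapping each camera frame into the virtual frame."""
    b = compute_barycenter(rig)
    T_1toV = RigidTransform(np.eye(3), -b)
    R12, t12 = rig.T_1to2.R, rig.T_1to2.t
    R13, t13 = rig.T_1to3.R, rig.T_1to3.t
    T_2toV = RigidTransform(R12.T, -R12.T @ t12 - b)
    T_3toV = RigidTransform(R13.T, -R13.T @ t13 - b)
    return T_1toV, T_2toV, T_3toV


def plane_in_frame(plane: PlaneSpec, T: RigidTransform, frame: Frame) -> PlaneSpec:
    """Re-express a plane through the rigid transform ``T`` (source = plane.frame).

    For ``x_dst = R x_src + t`` the same world plane becomes
    ``n_dst = R n_src`` and ``d_dst = d_src + n_dst . t``. Raises
    :class:`BehindCameraError` if the plane ends up behind the new origin.
    """
    n_dst = T.R @ plane.n
    d_dst = plane.d + float(n_dst @ T.t)
    if d_dst <= 0:
        raise BehindCameraError(
            f"plane lies behind the origin of frame {frame!r} (d = {d_dst:.3f} mm)"
        )
    return PlaneSpec(frame=frame, n=n_dst, d=d_dst)


def plane_from_virtual(plane: PlaneSpec, vcam: VirtualCamera) -> PlaneSpec:
    """Convert a plane given in the virtual frame to camera-1 coordinates."""
    if plane.frame != "V":
        raise ValueError("plane must be expressed in the virtual frame")
    return plane_in_frame(plane, invert(vcam.T_1toV), frame=1)


def _warped_corners(rig: TriRig, vcam: VirtualCamera, plane1: PlaneSpec) -> np.ndarray:
    """Map the four corners of each source image through the stitching maps."""
    from .homography import apply_homography, stitching_homographies

    Hs = stitching_homographies(rig, vcam, plane1)
    pts = []
    for cam, H in zip(rig.cameras, Hs):
        w, h = cam.size
        corners = np.array(
            [[0.0, 0.0], [w - 1.0, 0.0], [0.0, h - 1.0], [w - 1.0, h - 1.0]]
        )
        mapped, valid = apply_homography(H, corners)
        if not np.all(valid):
            raise BehindCameraError(
                "a source image corner maps behind the virtual camera; "
                "the homography plane is too close"
            )
        pts.append(mapped)
    return np.vstack(pts)


def fit_virtual_intrinsics(
    rig: TriRig,
    plane: PlaneSpec,
    margin_px: float = 0.0,
    mode: str = "auto",
) -> VirtualCamera:
    """Build the virtual camera for a homography plane given in frame 1.

    ``mode="fixed"`` pins K_v to camera-1's (distortion-free) intrinsics and
    the canvas to camera-1's size; this is what the quantitative evaluation
    uses. ``mode="auto"`` keeps camera-1's focal lengths but grows the canvas
    and recentres the principal point so the warped corners of all three
    undistorted source images fit inside with ``margin_px`` to spare.
    """
    if plane.frame != 1:
        raise ValueError("homography plane must be expressed in camera-1's frame")
    if mode not in ("auto", "fixed"):
        raise ValueError(f"mode must be 'auto' or 'fixed', got {mode!r}")

    T1, T2, T3 = virtual_poses(rig)
    K1 = rig.cam1
    fixed_K = CameraIntrinsics(
        fx=K1.fx, fy=K1.fy, cx=K1.cx, cy=K1.cy, skew=K1.skew,
        width=K1.width, height=K1.height, k1=0.0, k2=0.0,
    )
    vcam = VirtualCamera(K_v=fixed_K, T_1toV=T1, T_2toV=T2, T_3toV=T3)
    if mode == "fixed":
        # Still validate that the plane is in front of all three cameras.
        for i in (2, 3):
            plane_in_frame(plane, rig.transform_from_cam1(i), frame=i)
        return vcam

    corners = _warped_corners(rig, vcam, plane)
    lo = corners.min(axis=0) - margin_px
    hi = corners.max(axis=0) + margin_px
    width = int(np.ceil(hi[0] - lo[0])) + 1
    height = int(np.ceil(hi[1] - lo[1])) + 1
    width = max(width, K1.width)
    height = max(height, K1.height)
    auto_K = CameraIntrinsics(
        fx=K1.fx, fy=K1.fy,
        cx=K1.cx - lo[0], cy=K1.cy - lo[1],
        skew=K1.skew, width=width, height=height, k1=0.0, k2=0.0,
    )
    return VirtualCamera(K_v=auto_K, T_1toV=T1, T_2toV=T2, T_3toV=T3)
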