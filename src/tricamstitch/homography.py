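"""Plane-induced homographies between the rig cameras and the virtual camera.

For two pinhole cameras related by ``x_j = R x_i + t`` and a world plane
``n . x = d`` (unit normal and distance in camera-i coordinates, d > 0), the
images of on-plane points are related exactly by the 3x3 map

    H_ij = K_j (R + t n^T / d) K_i^{-1}

applied in homogeneous pixel coordinates, up to the usual projective scale.
This is the whole stitching engine: no feature detection or homography
estimation is involved. Off-plane content exhibits parallax; the misalignment
it causes is quantified in :mod:`tricamstitch.evaluation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera_model import CameraIntrinsics, RigidTransform, TriRig
from .rig_geometry import PlaneSpec, VirtualCamera, plane_in_frame

__all__ = [
    "Homography",
    "plane_induced_homography",
    "stitching_homographies",
    "apply_homography",
]

_LAMBDA_EPS = 1e-12


def _normalize(H: np.ndarray) -> np.ndarray:
    """Unit Frobenius norm; sign fixed so h33 > 0 when it is meaningfully nonzero."""
    H = H / np.linalg.norm(H)
    if abs(H[2, 2]) > 1e-12 and H[2, 2] < 0:
        H = -H
    return H


@dataclass(frozen=True)
class Homography:
    """A nonsingular 3x3 pixel-to-pixel projective map between two named frames."""

    H: np.ndarray
    src_frame: object
    dst_frame: object

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        if H.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {H.shape}")
        H = _normalize(H)
        if abs(np.linalg.det(H)) <= 1e-12:
            raise ValueError("homography is singular (degenerate plane or pose)")
        object.__setattr__(self, "H", H)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.H), self.dst_frame, self.src_frame)


def plane_induced_homography(
    K_i: CameraIntrinsics,
    K_j: CameraIntrinsics,
    T_itoj: RigidTransform,
    plane: PlaneSpec,
) -> Homography:
    """Closed-form homography mapping camera-i pixels to camera-j pixels.

    ``plane`` must be expressed in camera-i coordinates with ``d > 0``. The
    map is exact for scene content on the plane (pinhole images only — inputs
    must be undistorted first).
    """
    if plane.d <= 0:
        raise ValueError(f"plane distance must be positive, got d = {plane.d}")
    core = T_itoj.R + np.outer(T_itoj.t, plane.n) / plane.d
    H = K_j.K @ core @ K_i.K_inv
    return Homography(H, src_frame=plane.frame, dst_frame="?")


def stitching_homographies(
    rig: TriRig, vcam: VirtualCamera, plane: PlaneSpec
) -> tuple[Homography, Homography, Homography]:
    """The three maps H_1v, H_2v, H_3v for a homography plane given in frame 1."""
    if plane.frame != 1:
        raise ValueError("stitching plane must be expressed in camera-1's frame")
    out = []
    for i in (1, 2, 3):
        plane_i = (
            plane if i == 1 else plane_in_frame(plane, rig.transform_from_cam1(i), i)
        )
        H = plane_induced_homography(
            rig.cameras[i - 1].with_zero_distortion(),
            vcam.K_v,
            vcam.pose_from_camera(i),
            plane_i,
        )
        out.append(Homography(H.H, src_frame=i, dst_frame="V"))
    return tuple(out)


def apply_homography(
    H: Homography | np.ndarray, pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a homography to pixel points; returns (mapped_pts, valid_flags).

    Each point is lifted to homogeneous coordinates, multiplied by H and
    divided by the third component λ. Points with λ <= 1e-12 (mapping to
    infinity or behind the camera) are flagged invalid, with NaN coordinates,
    rather than raising.
    """
    M = H.H if isinstance(H, Homography) else np.asarray(H, dtype=float)
    pts = np.asarray(pts, dtype=float)
    single = pts.ndim == 1
    p = np.atleast_2d(pts)
    hom = np.hstack([p, np.ones((p.shape[0], 1))]) @ M.T
    lam = hom[:, 2]
    valid = lam > _LAMBDA_EPS
    out = np.full((p.shape[0], 2), np.nan)
    out[valid] = hom[valid, :2] / lam[valid, None]
    if single:
        return out[0], valid[0]
    return out, valid
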