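"""Core geometric types for the three-camera endoscopic rig.

Pinhole intrinsics with a two-coefficient radial distortion model (tangential
distortion is deliberately not modelled), rigid transforms between camera
frames, and a plain-text YAML calibration file that stores the outputs of a
standard plane-based calibration.

Conventions (pinned; tests rely on them):

* Pixels are 0-based; ``(0, 0)`` is the centre of the top-left pixel,
  ``u`` is the column index, ``v`` the row index.
* A :class:`RigidTransform` ``T`` maps coordinates as ``x_dst = R @ x_src + t``.
  Consequently the source-camera centre expressed in the destination frame is
  ``t`` and the destination centre in the source frame is ``-R.T @ t``.
* Translations are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "CameraIntrinsics",
    "RigidTransform",
    "TriRig",
    "BehindCameraError",
    "CalibrationSchemaError",
    "project_point",
    "distort_normalized",
    "undistort_normalized",
    "compose",
    "invert",
    "identity_transform",
    "read_calibration",
    "write_calibration",
]

_ROT_TOL = 1e-9


class BehindCameraError(ValueError):
    """A 3D point (or plane) lies at or behind the camera's principal plane."""


class CalibrationSchemaError(ValueError):
    """The calibration file is missing a field or violates an invariant."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics plus two radial distortion coefficients.

    Focal lengths and principal point are in pixels; ``k1``/``k2`` act on
    normalized image coordinates and are dimensionless.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    skew: float = 0.0
    k1: float = 0.0
    k2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (float(self.width).is_integer() and float(self.height).is_integer()):
            raise ValueError("image size must be integral")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        """The 3x3 intrinsic matrix."""
        return np.array(
            [
                [self.fx, self.skew, self.cx],
                [0.0, self.fy, self.cy],
                [0.0, 0.0, 1.0],
            ]
        )

    @property
    def K_inv(self) -> np.ndarray:
        return np.linalg.inv(self.K)

    @property
    def size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (int(self.width), int(self.height))

    def with_zero_distortion(self) -> "CameraIntrinsics":
        return replace(self, k1=0.0, k2=0.0)


def _check_rotation(R: np.ndarray, tol: float = _ROT_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > tol:
        raise ValueError("rotation matrix must have det +1 (no reflections)")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping ``x_dst = R @ x_src + t`` (t in mm)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", _check_rotation(self.R))
        t = np.asarray(self.t, dtype=float).reshape(3)
        object.__setattr__(self, "t", t)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Transform one (3,) point or an (N, 3) array of points."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.R.T + self.t

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.t
        return M


def identity_transform() -> RigidTransform:
    return RigidTransform(np.eye(3), np.zeros(3))


def compose(T_a: RigidTransform, T_b: RigidTransform) -> RigidTransform:
    """Chain two transforms: the result maps T_a's source frame through both.

    ``compose(T_a, T_b).apply(x) == T_b.apply(T_a.apply(x))``.
    """
    return RigidTransform(T_b.R @ T_a.R, T_b.R @ T_a.t + T_b.t)


def invert(T: RigidTransform) -> RigidTransform:
    return RigidTransform(T.R.T, -T.R.T @ T.t)


@dataclass(frozen=True)
class TriRig:
    """Three calibrated cameras; extrinsics map camera-1 coordinates outward."""

    cam1: CameraIntrinsics
    cam2: CameraIntrinsics
    cam3: CameraIntrinsics
    T_1to2: RigidTransform
    T_1to3: RigidTransform

    @property
    def cameras(self) -> tuple[CameraIntrinsics, CameraIntrinsics, CameraIntrinsics]:
        return (self.cam1, self.cam2, self.cam3)

    def transform_from_cam1(self, i: int) -> RigidTransform:
        """T mapping camera-1 coordinates into camera ``i`` (1-based)."""
        if i == 1:
            return identity_transform()
        if i == 2:
            return self.T_1to2
        if i == 3:
            return self.T_1to3
        raise ValueError(f"camera index must be 1, 2 or 3, got {i}")

    def camera_center_in_frame1(self, i: int) -> np.ndarray:
        """Camera ``i``'s optical centre expressed in camera-1 coordinates."""
        T = self.transform_from_cam1(i)
        return -T.R.T @ T.t


# ---------------------------------------------------------------------------
# distortion model
# ---------------------------------------------------------------------------

def distort_normalized(xn: np.ndarray, k1: float, k2: float) -> np.ndarray:
    """Apply the radial model ``x * (1 + k1 r^2 + k2 r^4)`` to normalized coords.

    Accepts a (2,) point or an (N, 2) array.
    """
    xn = np.asarray(xn, dtype=float)
    r2 = np.sum(xn * xn, axis=-1, keepdims=True)
    return xn * (1.0 + k1 * r2 + k2 * r2 * r2)


def undistort_normalized(
    xd: np.ndarray,
    k1: float,
    k2: float,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> np.ndarray:
    """Invert the radial model (damped Newton on the scalar radius).

    The model moves points only along the radius, so inversion reduces to
    solving ``r (1 + k1 r^2 + k2 r^4) = r_d`` for each observed radius and
    rescaling the direction. Newton steps are damped where the derivative
    gets small; raises if any point fails to reach ``tol`` within
    ``max_iter`` iterations (e.g. outside the invertible radius range).
    """
    xd = np.asarray(xd, dtype=float)
    if k1 == 0.0 and k2 == 0.0:
        return xd.copy()
    single = xd.ndim == 1
    target = np.atleast_2d(xd).astype(float)
    rd = np.linalg.norm(target, axis=-1)
    r = rd.copy()
    for _ in range(max_iter):
        r2 = r * r
        f = r * (1.0 + k1 * r2 + k2 * r2 * r2) - rd
        if np.max(np.abs(f)) < tol:
            break
        df = 1.0 + 3.0 * k1 * r2 + 5.0 * k2 * r2 * r2
        step = f / np.where(np.abs(df) > 0.05, df, np.sign(df + 1e-300) * 0.05)
        np.clip(step, -0.25 * (r + 0.1), 0.25 * (r + 0.1), out=step)
        r = np.maximum(r - step, 0.0)
    else:
        r2 = r * r
        f = r * (1.0 + k1 * r2 + k2 * r2 * r2) - rd
        bad = int(np.argmax(np.abs(f)))
        raise RuntimeError(
            f"undistort_normalized did not converge within {max_iter} "
            f"iterations for point {tuple(target[bad])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rd > 0, r / np.where(rd > 0, rd, 1.0), 1.0)
    out = target * scale[:, None]
    return out[0] if single else out


def project_point(
    p: np.ndarray, cam: CameraIntrinsics, apply_distortion: bool = True
) -> np.ndarray:
    """Project camera-frame point(s) (mm) to pixel coordinates.

    Accepts a (3,) point or (N, 3) array; every point must satisfy ``z > 0``.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    z = pts[:, 2]
    if np.any(z <= 0):
        raise BehindCameraError(
            "point(s) at or behind the camera (z <= 0) cannot be projected"
        )
    xn = pts[:, :2] / z[:, None]
    if apply_distortion:
        xn = distort_normalized(xn, cam.k1, cam.k2)
    ones = np.ones((xn.shape[0], 1))
    uv = np.hstack([xn, ones]) @ cam.K.T
    uv = uv[:, :2]
    return uv[0] if single else uv


# ---------------------------------------------------------------------------
# calibration file I/O
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1
_CAM_FIELDS = ("fx", "fy", "cx", "cy", "skew", "k1", "k2", "width", "height")


def _cam_to_dict(cam: CameraIntrinsics) -> dict:
    d = {f: float(getattr(cam, f)) for f in _CAM_FIELDS}
    d["width"] = int(cam.width)
    d["height"] = int(cam.height)
    return d


def _transform_to_dict(T: RigidTransform) -> dict:
    return {
        "R": [float(x) for x in T.R.reshape(9)],
        "t": [float(x) for x in T.t],
    }


def write_calibration(rig: TriRig, path) -> None:
    """Write a rig to a YAML calibration file (lossless 17-digit floats)."""
    doc = {
        "version": _SCHEMA_VERSION,
        "units": "mm",
        "cameras": {
            "cam1": _cam_to_dict(rig.cam1),
            "cam2": _cam_to_dict(rig.cam2),
            "cam3": _cam_to_dict(rig.cam3),
        },
        "extrinsics": {
            "1to2": _transform_to_dict(rig.T_1to2),
            "1to3": _transform_to_dict(rig.T_1to3),
        },
    }

    def _repr_float(dumper, value):
        return dumper.represent_scalar("tag:yaml.org,2002:float", repr(float(value)))

    class _Dumper(yaml.SafeDumper):
        pass

    _Dumper.add_representer(float, _repr_float)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.dump(doc, fh, Dumper=_Dumper, sort_keys=False)


def _require(mapping: dict, key: str, context: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise CalibrationSchemaError(f"calibration file is missing '{key}' in {context}")
    return mapping[key]


def _read_camera(block: dict, name: str) -> CameraIntrinsics:
    vals = {f: _require(block, f, name) for f in _CAM_FIELDS}
    try:
        return CameraIntrinsics(
            fx=float(vals["fx"]),
            fy=float(vals["fy"]),
            cx=float(vals["cx"]),
            cy=float(vals["cy"]),
            skew=float(vals["skew"]),
            k1=float(vals["k1"]),
            k2=float(vals["k2"]),
            width=int(vals["width"]),
            height=int(vals["height"]),
        )
    except ValueError as exc:
        raise CalibrationSchemaError(f"invalid intrinsics for {name}: {exc}") from exc


def _read_transform(block: dict, name: str) -> RigidTransform:
    R = np.asarray(_require(block, "R", name), dtype=float)
    t = np.asarray(_require(block, "t", name), dtype=float)
    if R.size != 9:
        raise CalibrationSchemaError(f"'R' in {name} must have 9 numbers")
    if t.size != 3:
        raise CalibrationSchemaError(f"'t' in {name} must have 3 numbers")
    R = R.reshape(3, 3)
    # Accept tiny serialization round-off, reject anything structurally wrong.
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise CalibrationSchemaError(
            f"'R' in {name} is not a proper rotation (orthonormal, det +1)"
        )
    try:
        return RigidTransform(R, t)
    except ValueError:
        # Re-orthonormalize via SVD only within the 1e-6 acceptance band.
        U, _, Vt = np.linalg.svd(R)
        return RigidTransform(U @ Vt, t)


def read_calibration(path) -> TriRig:
    """Read and validate a YAML calibration file written by :func:`write_calibration`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise CalibrationSchemaError("calibration file is not a mapping")
    _require(doc, "version", "top level")
    units = _require(doc, "units", "top level")
    if units != "mm":
        raise CalibrationSchemaError(f"units must be 'mm', got {units!r}")
    cams = _require(doc, "cameras", "top level")
    ext = _require(doc, "extrinsics", "top level")
    return TriRig(
        cam1=_read_camera(_require(cams, "cam1", "cameras"), "cam1"),
        cam2=_read_camera(_require(cams, "cam2", "cameras"), "cam2"),
        cam3=_read_camera(_require(cams, "cam3", "cameras"), "cam3"),
        T_1to2=_read_transform(_require(ext, "1to2", "extrinsics"), "extrinsics/1to2"),
        T_1to3=_read_transform(_require(ext, "1to3", "extrinsics"), "extrinsics/1to3"),
    )
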