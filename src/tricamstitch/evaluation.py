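"""Quantitative stitch-misalignment evaluation on chessboard targets.

The protocol: place a chessboard parallel to the virtual image plane at a
known distance along the virtual optical axis, project its inner corners
into each camera, map homologous corners through the per-camera stitching
homographies (computed once, for the fixed homography-plane distance), and
measure the Euclidean distance between the two mapped positions for every
camera pair. On the homography plane this distance is zero up to numerical
error for exact calibration; off the plane it grows with the parallax term
|1/z - 1/d|. Results are reported per pair and pooled, in px and as a
percentage of the warped image side.

Distance convention: both the homography-plane distance and the board
distances are measured from the *virtual* camera along its optical axis.
The navigation stitcher specifies its plane from camera 1 instead; in the
default converged rig the two origins differ by a few mm along the viewing
axis, and this module's convention is the one that puts the error minimum
exactly at the nominal plane distance.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera_model import RigidTransform, TriRig, undistort_normalized
from .homography import Homography, apply_homography
from .rig_geometry import (
    PlaneSpec,
    VirtualCamera,
    compute_barycenter,
    fit_virtual_intrinsics,
)
from .synthetic_rig import (
    ChessboardSpec,
    GroundTruth,
    RigSpec,
    make_default_rig,
    perturb_calibration,
    project_board,
)

__all__ = [
    "PairStats",
    "MisalignmentReport",
    "SweepConfig",
    "corner_misalignment",
    "depth_sweep",
    "write_report",
    "read_report",
    "plot_error_trend",
    "benchmark_stitch",
    "PAIRS",
]

PAIRS = ((1, 2), (1, 3), (2, 3))


class InsufficientOverlapError(ValueError):
    """No chessboard corner is visible in both cameras of any pair."""


@dataclass(frozen=True)
class PairStats:
    """Misalignment statistics for one camera pair (population std)."""

    pair: tuple[int, int]
    mean_px: float
    std_px: float
    n: int


def _undistort_pixels(px: np.ndarray, cam) -> np.ndarray:
    """Map distorted pixel observations to ideal pinhole pixels."""
    if cam.k1 == 0.0 and cam.k2 == 0.0:
        return px
    ones = np.ones((px.shape[0], 1))
    xn = np.hstack([px, ones]) @ cam.K_inv.T
    xu = undistort_normalized(xn[:, :2], cam.k1, cam.k2)
    K0 = cam.with_zero_distortion()
    return np.hstack([xu, ones]) @ K0.K.T[:, :2]


def corner_misalignment(
    gt: GroundTruth,
    homographies: tuple[Homography, Homography, Homography],
    vcam: VirtualCamera,
) -> dict[tuple[int, int], PairStats]:
    """Pairwise corner misalignment on the virtual canvas, in px.

    For each pair (i, j) and every corner visible in both views, the
    (undistorted) corner pixels are mapped through H_iv and H_jv and the
    Euclidean distance between the two canvas positions is recorded.
    """
    mapped = []
    for i in (1, 2, 3):
        cam = gt.rig.cameras[i - 1]
        px = _undistort_pixels(gt.pixels[i - 1], cam)
        pts, valid = apply_homography(homographies[i - 1], px)
        mapped.append((pts, valid & gt.visible[i - 1]))

    out: dict[tuple[int, int], PairStats] = {}
    for i, j in PAIRS:
        pi, vi = mapped[i - 1]
        pj, vj = mapped[j - 1]
        both = vi & vj
        if not both.any():
            continue
        d = np.linalg.norm(pi[both] - pj[both], axis=1)
        out[(i, j)] = PairStats(
            pair=(i, j),
            mean_px=float(d.mean()),
            std_px=float(d.std()),  # population std
            n=int(both.sum()),
        )
    if not out:
        raise InsufficientOverlapError(
            "no corner is visible in both cameras of any pair"
        )
    return out


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of the depth sweep (distances from the virtual camera)."""

    homography_distance_mm: float = 40.0
    distances_mm: tuple[float, ...] = tuple(np.arange(30.0, 50.0 + 1e-9, 2.5))
    board: ChessboardSpec = field(default_factory=ChessboardSpec)
    rig: TriRig | None = None  # None -> default synthetic rig
    rig_spec: RigSpec | None = None
    kv_mode: str = "fixed"
    rot_noise_deg: float = 0.0
    trans_noise_mm: float = 0.0
    intrinsics_noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.homography_distance_mm <= 0:
            raise ValueError("homography distance must be positive")
        if any(d <= 0 for d in self.distances_mm):
            raise ValueError("all sweep distances must be positive")


@dataclass
class MisalignmentReport:
    """Tidy per-distance, per-pair misalignment table.

    Columns: distance_mm, pair ('1-2', '1-3', '2-3', 'mean'), mean_px,
    std_px, mean_pct, std_pct, n. Percentages are relative to the warped
    image side (the canvas width). The 'mean' rows pool the pairs with an
    unweighted average of the pair means (and of the pair stds).
    """

    table: pd.DataFrame
    canvas_side: int
    homography_distance_mm: float

    def pooled_mean_pct(self, distance_mm: float) -> float:
        sel = self.table[
            (self.table["pair"] == "mean")
            & np.isclose(self.table["distance_mm"], distance_mm)
        ]
        if sel.empty:
            raise KeyError(f"no pooled row at {distance_mm} mm")
        return float(sel["mean_pct"].iloc[0])


def _board_at_depth(board: ChessboardSpec, z_mm: float,
                    vcam: VirtualCamera) -> ChessboardSpec:
    """Place the board parallel to the virtual image plane, centred on the
    virtual axis, ``z_mm`` ahead of the virtual camera (pose in frame 1)."""
    b = -vcam.T_1toV.t  # virtual centre in frame 1
    from dataclasses import replace

    return replace(
        board, pose=RigidTransform(np.eye(3), b + np.array([0.0, 0.0, z_mm]))
    )


def depth_sweep(cfg: SweepConfig) -> MisalignmentReport:
    """Run the chessboard depth sweep and collect the misalignment table.

    Ground-truth corners come from the true rig; the homographies (and the
    virtual camera) are computed from the — optionally perturbed —
    calibration, so nonzero noise emulates residual calibration error.
    """
    from .homography import stitching_homographies

    rig_true = cfg.rig if cfg.rig is not None else make_default_rig(cfg.rig_spec)
    rig_calib = perturb_calibration(
        rig_true, cfg.rot_noise_deg, cfg.trans_noise_mm,
        cfg.intrinsics_noise_frac, seed=cfg.seed,
    )

    # Homography plane: parallel to the virtual image plane, at the nominal
    # distance along the virtual axis. Re-express in frame 1 (shared
    # orientation, origin offset by the barycenter b).
    ez = np.array([0.0, 0.0, 1.0])
    b_calib = compute_barycenter(rig_calib)
    plane1 = PlaneSpec(frame=1, n=ez,
                       d=cfg.homography_distance_mm + float(ez @ b_calib))
    vcam = fit_virtual_intrinsics(rig_calib, plane1, mode=cfg.kv_mode)
    Hs = stitching_homographies(rig_calib, vcam, plane1)

    # Board placement uses the *true* rig geometry (the physical axis).
    b_true = compute_barycenter(rig_true)
    vcam_true = fit_virtual_intrinsics(
        rig_true, PlaneSpec(frame=1, n=ez, d=cfg.homography_distance_mm
                            + float(ez @ b_true)),
        mode="fixed",
    )

    rows = []
    for z in cfg.distances_mm:
        board = _board_at_depth(cfg.board, z, vcam_true)
        gt = project_board(rig_true, board)
        stats = corner_misalignment(gt, Hs, vcam)
        side = vcam.canvas_size[0]
        means, stds = [], []
        for (i, j) in PAIRS:
            if (i, j) not in stats:
                continue
            s = stats[(i, j)]
            rows.append(
                dict(distance_mm=z, pair=f"{i}-{j}", mean_px=s.mean_px,
                     std_px=s.std_px, mean_pct=s.mean_px / side * 100.0,
                     std_pct=s.std_px / side * 100.0, n=s.n)
            )
            means.append(s.mean_px)
            stds.append(s.std_px)
        pooled_mean = float(np.mean(means))
        pooled_std = float(np.mean(stds))
        pooled_n = int(min(s.n for s in stats.values()))
        rows.append(
            dict(distance_mm=z, pair="mean", mean_px=pooled_mean,
                 std_px=pooled_std, mean_pct=pooled_mean / side * 100.0,
                 std_pct=pooled_std / side * 100.0, n=pooled_n)
        )
    return MisalignmentReport(
        table=pd.DataFrame(rows),
        canvas_side=vcam.canvas_size[0],
        homography_distance_mm=cfg.homography_distance_mm,
    )


def write_report(report: MisalignmentReport, path) -> None:
    """Write the report as CSV (12 significant digits, '.' decimal)."""
    if report.table.empty:
        raise ValueError("cannot write an empty report")
    report.table.to_csv(path, index=False, float_format="%.12g")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


def plot_error_trend(report: MisalignmentReport, path) -> None:
    """Error-trend plot per camera pair; error bars are +/- 2 std."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.table.empty:
        raise ValueError("cannot plot an empty report")
    pairs = [p for p in ("1-2", "1-3", "2-3") if (report.table["pair"] == p).any()]
    fig, axes = plt.subplots(1, max(len(pairs), 1), figsize=(4 * len(pairs), 3.2),
                             sharey=True, squeeze=False)
    for ax, pair in zip(axes[0], pairs):
        sub = report.table[report.table["pair"] == pair]
        ax.errorbar(sub["distance_mm"], sub["mean_px"], yerr=2 * sub["std_px"],
                    fmt="o-", capsize=3)
        ax.axvline(report.homography_distance_mm, ls="--", c="grey", lw=0.8)
        ax.set_title(f"Cameras {pair}")
        ax.set_xlabel("Distance from virtual camera (mm)")
    axes[0][0].set_ylabel("Misalignment (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def benchmark_stitch(rig: TriRig, vcam: VirtualCamera, config=None,
                     n_frames: int = 20, seed: int = 0) -> dict:
    """Mean/std wall-clock time per stitched frame, on random noise inputs.

    Informational only — timings are hardware-dependent.
    """
    from .stitcher import StitchConfig, stitch_frame

    config = config or StitchConfig()
    rng = np.random.default_rng(seed)
    images = tuple(
        rng.uniform(0, 255, size=(cam.height, cam.width)) for cam in rig.cameras
    )
    stitch_frame(images, rig, vcam, config)  # warm-up
    times = []
    for _ in range(n_frames):
        t0 = time.perf_counter()
        stitch_frame(images, rig, vcam, config)
        times.append(time.perf_counter() - t0)
    times = np.asarray(times)
    return {
        "mean_ms": float(times.mean() * 1e3),
        "std_ms": float(times.std() * 1e3),
        "n_frames": int(n_frames),
    }
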