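import numpy as np
import pytest

from tricamstitch.camera_model import CameraIntrinsics, RigidTransform, TriRig
from tricamstitch.synthetic_rig import RigSpec, default_intrinsics, make_default_rig


def random_rotation(rng: np.random.Generator, max_deg: float = 25.0) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_deg, max_deg))
    vx = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * vx + (1 - np.cos(angle)) * vx @ vx


def random_rig(rng: np.random.Generator) -> TriRig:
    """A plausible random three-camera rig: mild tilts, mm-scale baselines."""
    cam = default_intrinsics()
    T12 = RigidTransform(random_rotation(rng), rng.uniform(-8, 8, 3))
    T13 = RigidTransform(random_rotation(rng), rng.uniform(-8, 8, 3))
    return TriRig(cam1=cam, cam2=cam, cam3=cam, T_1to2=T12, T_1to3=T13)


@pytest.fixture(scope="session")
def default_rig() -> TriRig:
    """The converged synthetic rig the evaluation uses."""
    return make_default_rig()


@pytest.fixture(scope="session")
def parallel_rig() -> TriRig:
    return make_default_rig(RigSpec(tilt_mode="parallel"))


@pytest.fixture(scope="session")
def identity_rig() -> TriRig:
    """Three coincident cameras (degenerate zero-baseline limit)."""
    cam = default_intrinsics()
    ident = RigidTransform(np.eye(3), np.zeros(3))
    return TriRig(cam1=cam, cam2=cam, cam3=cam, T_1to2=ident, T_1to3=ident)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
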