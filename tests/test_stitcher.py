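import numpy as np
import pytest

from tricamstitch.camera_model import RigidTransform, TriRig
from tricamstitch.homography import Homography
from tricamstitch.rig_geometry import PlaneSpec, fit_virtual_intrinsics
from tricamstitch.stitcher import (
    StitchConfig,
    align_horizons,
    blend,
    euler_z_angle,
    stitch_frame,
    warp_image,
)
from tricamstitch.synthetic_rig import (
    ChessboardSpec,
    default_intrinsics,
    render_chessboard,
)


def rot_z(deg):
    a = np.deg2rad(deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]]
    )


class TestWarpImage:
    def test_identity_reproduces_source(self, rng):
        src = rng.uniform(0, 255, (50, 60))
        layer = warp_image(src, Homography(np.eye(3), 1, "V"), (60, 50))
        assert layer.mask.all()
        assert np.allclose(layer.image, src, atol=1e-9)

    @pytest.mark.parametrize("interp", ["nearest", "bilinear"])
    def test_pure_translation_shifts_and_unmasks_band(self, rng, interp):
        src = rng.uniform(0, 255, (40, 40))
        M = np.array([[1.0, 0, 5.0], [0, 1.0, 0], [0, 0, 1.0]])
        layer = warp_image(src, Homography(M, 1, "V"), (40, 40), interp)
        assert not layer.mask[:, :5].any()
        assert layer.mask[:, 5:].all()
        assert np.allclose(layer.image[:, 5:], src[:, :35], atol=1e-9)
        assert np.all(layer.image[:, :5] == 0)

    @pytest.mark.parametrize("interp", ["nearest", "bilinear"])
    def test_constant_source_stays_constant(self, interp):
        src = np.full((30, 30), 77.0)
        M = np.array([[0.9, 0.1, 3.0], [-0.05, 1.1, -2.0], [1e-4, 0, 1.0]])
        layer = warp_image(src, Homography(M, 1, "V"), (40, 40), interp)
        assert layer.mask.any()
        assert np.allclose(layer.image[layer.mask], 77.0, atol=1e-9)
        assert np.all(layer.image[~layer.mask] == 0)


class TestBlend:
    def make_layer(self, value, mask, canvas=(30, 30)):
        img = np.where(mask, float(value), 0.0)
        ys, xs = np.nonzero(mask)
        cx = xs.mean() if xs.size else 0.0
        cy = ys.mean() if ys.size else 0.0
        uu, vv = np.meshgrid(np.arange(canvas[1]), np.arange(canvas[0]))
        dist = np.where(mask, np.hypot(uu - cx, vv - cy), np.inf)
        from tricamstitch.stitcher import WarpedLayer

        return WarpedLayer(image=img, mask=mask, source=0, center_dist=dist)

    def masks(self):
        m1 = np.zeros((30, 30), bool)
        m2 = np.zeros((30, 30), bool)
        m1[:, :20] = True
        m2[:, 10:] = True
        return m1, m2

    @pytest.mark.parametrize("mode", ["feathered", "hard_lines"])
    def test_single_covering_layer_passthrough(self, mode):
        m = np.zeros((30, 30), bool)
        m[5:25, 5:25] = True
        layers = [
            self.make_layer(150, m),
            self.make_layer(0, np.zeros((30, 30), bool)),
            self.make_layer(0, np.zeros((30, 30), bool)),
        ]
        out = blend(layers, StitchConfig(blend_mode=mode))
        assert np.allclose(out[m], 150.0)
        assert np.all(out[~m] == 0)

    def test_feathered_partition_of_unity_and_monotone(self):
        m1, m2 = self.masks()
        layers = [self.make_layer(100, m1), self.make_layer(200, m2)]
        cfg = StitchConfig(blend_mode="feathered", feather_width=8)
        out = blend(layers, cfg)
        covered = m1 | m2
        # Convexity: output bounded by contributing values, hence weights
        # summing to one wherever covered.
        assert np.all(out[covered] >= 100.0 - 1e-6)
        assert np.all(out[covered] <= 200.0 + 1e-6)
        assert np.allclose(out[m1 & ~m2], 100.0)
        assert np.allclose(out[m2 & ~m1], 200.0)
        # Monotone transition across the overlap along each row.
        row = out[15, 10:20]
        assert np.all(np.diff(row) >= -1e-9)

    def test_feathered_weight_sum_audit(self):
        from tricamstitch.stitcher import _feather_weights

        m1, m2 = self.masks()
        layers = [self.make_layer(100, m1), self.make_layer(200, m2)]
        w = _feather_weights(layers, 8.0)
        covered = m1 | m2
        assert np.allclose(w.sum(axis=0)[covered], 1.0, atol=1e-6)
        assert np.allclose(w.sum(axis=0)[~covered], 0.0)

    def test_hard_mode_single_source_rule(self):
        m1, m2 = self.masks()
        layers = [self.make_layer(100, m1), self.make_layer(200, m2)]
        out = blend(layers, StitchConfig(blend_mode="hard_lines"))
        covered = m1 | m2
        seam = covered & (out == 0.0)  # default seam colour is black
        vals = out[covered & ~seam]
        assert set(np.unique(vals)) <= {100.0, 200.0}
        assert seam.sum() > 0  # a seam exists between the two regions

    def test_mismatched_canvas_rejected(self):
        a = self.make_layer(1, np.ones((30, 30), bool))
        b = self.make_layer(1, np.ones((20, 30), bool), canvas=(20, 30))
        with pytest.raises(ValueError, match="mismatch"):
            blend([a, b], StitchConfig())


class TestStitchFrame:
    def test_identity_rig_identical_images_passthrough(self, identity_rig, rng):
        img = rng.uniform(0, 255, (400, 400))
        vcam = fit_virtual_intrinsics(
            identity_rig, PlaneSpec(1, [0, 0, 1.0], 40.0), mode="fixed"
        )
        out = stitch_frame((img, img, img), identity_rig, vcam,
                           StitchConfig(plane_distance_mm=40.0))
        assert np.allclose(out, img, atol=1e-6)

    def test_deterministic(self, default_rig, rng):
        imgs = tuple(rng.uniform(0, 255, (400, 400)) for _ in range(3))
        vcam = fit_virtual_intrinsics(
            default_rig, PlaneSpec(1, [0, 0, 1.0], 40.0), mode="fixed"
        )
        a = stitch_frame(imgs, default_rig, vcam)
        b = stitch_frame(imgs, default_rig, vcam)
        assert np.array_equal(a, b)

    def test_on_plane_scene_matches_direct_virtual_render(self, default_rig):
        """A chessboard lying on the homography plane, stitched from the
        three real views, must reproduce the virtual camera's own rendering
        of that board up to interpolation error."""
        from tricamstitch.rig_geometry import compute_barycenter
        from tricamstitch.synthetic_rig import _render_one
        from tricamstitch.camera_model import compose, invert

        b = compute_barycenter(default_rig)
        d_v = 40.0
        plane1 = PlaneSpec(1, [0.0, 0.0, 1.0], d_v + b[2])
        vcam = fit_virtual_intrinsics(default_rig, plane1, mode="fixed")
        board = ChessboardSpec(
            pose=RigidTransform(np.eye(3), b + np.array([0.0, 0.0, d_v]))
        )
        images, _ = render_chessboard(default_rig, board)
        cfg = StitchConfig(blend_mode="feathered", plane_distance_mm=plane1.d)
        stitched = stitch_frame(tuple(images), default_rig, vcam, cfg)

        T_b_to_virtual = compose(board.pose, vcam.T_1toV)
        direct = _render_one(vcam.K_v, T_b_to_virtual, board, 4, 128.0)
        # Restrict the comparison to canvas pixels actually covered by at
        # least one warped view (constant-white probe marks coverage).
        white = np.full((400, 400), 255.0)
        coverage = stitch_frame((white,) * 3, default_rig, vcam, cfg) > 254.0
        assert coverage.mean() > 0.5
        diff = np.abs(stitched - direct)[coverage]
        assert diff.mean() < 2.0

    def test_wrong_image_size_rejected(self, default_rig):
        vcam = fit_virtual_intrinsics(
            default_rig, PlaneSpec(1, [0, 0, 1.0], 40.0), mode="fixed"
        )
        bad = (np.zeros((100, 100)),) * 3
        with pytest.raises(ValueError, match="size"):
            stitch_frame(bad, default_rig, vcam)


class TestAlignHorizons:
    def make_rig(self, R12, R13=None):
        cam = default_intrinsics()
        return TriRig(
            cam1=cam, cam2=cam, cam3=cam,
            T_1to2=RigidTransform(R12, np.zeros(3)),
            T_1to3=RigidTransform(np.eye(3) if R13 is None else R13, np.zeros(3)),
        )

    def test_identity_rotation_leaves_image(self, rng):
        rig = self.make_rig(np.eye(3))
        img = rng.uniform(0, 255, (400, 400))
        out = align_horizons((img, img, img), rig)
        assert np.array_equal(out[1], img)

    def test_pure_z_rotation_extracted_and_applied(self):
        rig = self.make_rig(rot_z(30.0))
        assert np.isclose(euler_z_angle(rig.T_1to2.R.T), np.deg2rad(-30.0),
                          atol=1e-9)
        img = np.zeros((400, 400))
        img[199, 299] = 255.0  # point at +100 px along u from the centre
        out = align_horizons((img, img, img), rig)
        # The point must move to centre + Rot(-30 deg) * (100, 0).
        expect = np.array([199.5, 199.5]) + 100 * np.array(
            [np.cos(np.deg2rad(-30)), np.sin(np.deg2rad(-30))]
        )
        v, u = np.unravel_index(np.argmax(out[1]), out[1].shape)
        assert np.hypot(u - expect[0], v - expect[1]) < 1.5

    def test_pure_x_tilt_leaves_image(self, rng):
        a = np.deg2rad(20)
        Rx = np.array(
            [[1.0, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
        )
        rig = self.make_rig(np.eye(3), R13=Rx)
        assert euler_z_angle(rig.T_1to3.R.T) == pytest.approx(0.0, abs=1e-12)
        img = rng.uniform(0, 255, (400, 400))
        out = align_horizons((img, img, img), rig)
        assert np.array_equal(out[2], img)
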