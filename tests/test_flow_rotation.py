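"""Optical-flow rotation tracking: flow contract, affine decomposition
oracle, calibration, accumulation."""
import numpy as np
import pytest

from endopose.flow_rotation import (DEAD_BAND, FlowCalibration, FlowField,
                                    NoTargetFlowError, TrajectoryEstimate,
                                    calibrate, decompose_motion, dense_flow,
                                    evaluate_trajectory, flow_to_rotation,
                                    masked_flow, track_sequence)
from endopose.localization import fit_ellipse
from endopose.scene_sim import Pose6D, generate_sequence


def _textured(shape=(64, 64), seed=0, smooth=2.0):
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.random(shape), smooth)
    img = (img - img.min()) / (img.max() - img.min())
    return (img * 255).astype(np.uint8)


class TestDenseFlow:
    def test_identical_frames_give_zero_flow(self):
        img = _textured()
        f = dense_flow(img, img)
        assert np.median(f.magnitude) < 0.05

    def test_one_pixel_shift_contract(self):
        img = _textured()
        shifted = np.roll(img, 1, axis=1)
        f = dense_flow(img, shifted)
        # judge over high-texture pixels (interior, away from wrap edge)
        sel = np.zeros(img.shape, bool)
        sel[8:-8, 8:-8] = True
        assert 0.8 <= np.median(f.du[sel]) <= 1.2
        assert -0.2 <= np.median(f.dv[sel]) <= 0.2

    def test_inplane_rotation_recovers_curl(self):
        from skimage.transform import rotate
        img = _textured((96, 96), seed=1)
        yy, xx = np.mgrid[0:96, 0:96]
        disk = ((xx - 47.5) ** 2 + (yy - 47.5) ** 2 <= 40 ** 2)
        img = np.where(disk, img, 0).astype(np.uint8)
        rot = rotate(img.astype(float), 2.0, center=(47.5, 47.5), order=1)
        f = dense_flow(img, rot.astype(np.uint8))
        mask = np.where(disk, 2, 0).astype(np.uint8)
        mf = masked_flow(f, mask, erode=7)
        d = decompose_motion(mf, fit_ellipse(disk))
        # skimage's on-screen CCW rotation is a positive model-Z rotation
        assert -np.degrees(d.curl) == pytest.approx(2.0, rel=0.2)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dense_flow(np.zeros((32, 32)), np.zeros((64, 64)))


class TestMaskedFlow:
    def test_no_target_class_raises(self):
        f = FlowField(du=np.zeros((8, 8), np.float32),
                      dv=np.zeros((8, 8), np.float32))
        with pytest.raises(NoTargetFlowError):
            masked_flow(f, np.zeros((8, 8), np.uint8))

    def test_full_frame_target_keeps_all_pixels(self):
        f = FlowField(du=np.ones((8, 8), np.float32),
                      dv=np.zeros((8, 8), np.float32))
        mf = masked_flow(f, np.full((8, 8), 2, np.uint8))
        assert mf.n == 64

    def test_intersection_of_both_masks(self):
        f = FlowField(du=np.zeros((8, 8), np.float32),
                      dv=np.zeros((8, 8), np.float32))
        m0 = np.zeros((8, 8), np.uint8)
        m1 = np.zeros((8, 8), np.uint8)
        m0[:4] = 2
        m1[2:6] = 2
        assert masked_flow(f, m0, m1).n == 16

    def test_covers_most_of_simulator_silhouette(self, z_sequence):
        f0, f1 = z_sequence.frames[0], z_sequence.frames[1]
        flow = dense_flow(f0.image, f1.image)
        mf = masked_flow(flow, f0.mask, f1.mask)
        smaller = min((f0.mask == 2).sum(), (f1.mask == 2).sum())
        assert mf.n >= 0.9 * smaller


class TestDecomposeMotion:
    def _grid_flow(self, fn, shape=(60, 60)):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        du, dv = fn(xx, yy)
        return FlowField(du=du.astype(np.float32), dv=dv.astype(np.float32))

    def test_analytic_rotation_field(self):
        w0 = 0.0349
        cx = cy = 29.5
        f = self._grid_flow(lambda x, y: (-w0 * (y - cy), w0 * (x - cx)))
        mask = np.full((60, 60), 2, np.uint8)
        d = decompose_motion(masked_flow(f, mask), fit_ellipse(mask == 2))
        assert d.curl == pytest.approx(w0, abs=1e-6)
        assert d.t == pytest.approx([0, 0], abs=1e-9)
        assert d.divergence == pytest.approx(0, abs=1e-9)

    def test_uniform_translation_with_center_motion(self):
        f = self._grid_flow(lambda x, y: (3 * np.ones_like(x), np.zeros_like(y)))
        mask = np.full((60, 60), 2, np.uint8)
        d = decompose_motion(masked_flow(f, mask), fit_ellipse(mask == 2),
                             center_displacement=(3.0, 0.0))
        assert d.curl == pytest.approx(0, abs=1e-9)
        assert d.slip == pytest.approx([0, 0], abs=1e-9)

    def test_zero_field_gives_zero_components(self):
        f = self._grid_flow(lambda x, y: (np.zeros_like(x), np.zeros_like(y)))
        mask = np.full((60, 60), 2, np.uint8)
        d = decompose_motion(masked_flow(f, mask), fit_ellipse(mask == 2))
        assert (d.curl, d.divergence) == (0, 0)
        assert np.all(d.A == 0) and np.all(d.t == 0)

    def test_general_affine_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        A0 = rng.normal(0, 0.05, (2, 2))
        t0 = rng.normal(0, 1, 2)
        cx = cy = 29.5
        f = self._grid_flow(lambda x, y: (
            A0[0, 0] * (x - cx) + A0[0, 1] * (y - cy) + t0[0],
            A0[1, 0] * (x - cx) + A0[1, 1] * (y - cy) + t0[1]))
        mask = np.full((60, 60), 2, np.uint8)
        d = decompose_motion(masked_flow(f, mask), fit_ellipse(mask == 2))
        assert d.A == pytest.approx(A0, abs=1e-6)
        assert d.t == pytest.approx(t0, abs=1e-6)

    def test_too_few_pixels_rejected(self):
        f = FlowField(du=np.zeros((8, 8), np.float32),
                      dv=np.zeros((8, 8), np.float32))
        mask = np.zeros((8, 8), np.uint8)
        mask[0, :5] = 2
        with pytest.raises(ValueError):
            decompose_motion(masked_flow(f, mask), fit_ellipse(mask == 2))


class TestFlowToRotation:
    CAL = FlowCalibration(kx=0.5, ky=0.5)

    def _decomp(self, curl=0.0, slip=(0.0, 0.0)):
        from endopose.flow_rotation import MotionDecomposition
        return MotionDecomposition(A=np.zeros((2, 2)), t=np.zeros(2),
                                   curl=curl, divergence=0.0,
                                   slip=np.asarray(slip, float))

    def test_curl_to_z_degrees(self):
        inc = flow_to_rotation(self._decomp(curl=0.0349), self.CAL)
        assert inc == pytest.approx([0, 0, -2.0], abs=1e-3)

    def test_slip_to_xy(self):
        inc = flow_to_rotation(self._decomp(slip=(2.0, 0.0)),
                               FlowCalibration(kx=0.5, ky=0.5))
        assert inc == pytest.approx([0, 1.0, 0])

    def test_zero_decomposition_is_zero(self):
        assert np.all(flow_to_rotation(self._decomp(), self.CAL) == 0)

    def test_dead_band_zeroes_small_slip(self):
        inc = flow_to_rotation(self._decomp(slip=(DEAD_BAND / 2, 0)), self.CAL)
        assert inc[1] == 0.0

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            FlowCalibration(kx=-1, ky=1)


@pytest.fixture(scope="module")
def calib(organ_mesh, clean_scene, center_pose):
    seqx = generate_sequence(organ_mesh, center_pose, (0.5, 0, 0), 15,
                             clean_scene, seed=11)
    seqy = generate_sequence(organ_mesh, center_pose, (0, 0.5, 0), 15,
                             clean_scene, seed=12)
    return calibrate({"x": (seqx.images, seqx.masks),
                      "y": (seqy.images, seqy.masks)},
                     {"x": 0.5, "y": 0.5})


class TestCalibrationAndTracking:
    def test_calibration_positive(self, calib):
        assert calib.kx > 0 and calib.ky > 0

    def test_static_sequence_has_no_usable_slip(self, static_sequence):
        with pytest.raises(ValueError, match="no usable slip"):
            calibrate({"x": (static_sequence.images, static_sequence.masks)},
                      {"x": 0.5})

    def test_static_tracking_stays_at_init(self, static_sequence, calib,
                                           center_pose):
        est = track_sequence(static_sequence.images, static_sequence.masks,
                             center_pose, calib)
        assert np.abs(est.angles - center_pose.rotations).max() <= 1.0

    def test_pure_z_accumulation(self, organ_mesh, clean_scene, center_pose,
                                 calib):
        seq = generate_sequence(organ_mesh, center_pose, (0, 0, 0.5), 25,
                                clean_scene, seed=31)
        est = track_sequence(seq.images, seq.masks, center_pose, calib)
        true_final = seq.trajectory[-1, 2]
        assert est.angles[-1, 2] == pytest.approx(true_final, abs=2.5)

    def test_additivity_of_halves(self, z_sequence, calib, center_pose):
        full = track_sequence(z_sequence.images, z_sequence.masks,
                              center_pose, calib)
        k = 6
        first = track_sequence(z_sequence.images[:k + 1],
                               z_sequence.masks[:k + 1], center_pose, calib)
        mid = center_pose.with_rotations(first.angles[-1])
        second = track_sequence(z_sequence.images[k:], z_sequence.masks[k:],
                                mid, calib)
        assert np.allclose(second.angles[-1], full.angles[-1], atol=1e-9)

    def test_reversed_sequence_negates_z(self, z_sequence, calib, center_pose):
        fwd = track_sequence(z_sequence.images, z_sequence.masks,
                             center_pose, calib)
        rev = track_sequence(z_sequence.images[::-1], z_sequence.masks[::-1],
                             center_pose, calib)
        dz_f = fwd.angles[-1, 2] - fwd.angles[0, 2]
        dz_r = rev.angles[-1, 2] - rev.angles[0, 2]
        assert dz_r == pytest.approx(-dz_f, rel=0.15)

    def test_single_frame_rejected(self, calib, center_pose):
        with pytest.raises(ValueError):
            track_sequence([np.zeros((64, 64, 3), np.uint8)],
                           [np.zeros((64, 64), np.uint8)], center_pose, calib)


class TestEvaluateTrajectory:
    def test_perfect_estimate_scores_one(self):
        traj = np.cumsum(np.full((30, 3), 0.2), axis=0)
        est = TrajectoryEstimate(angles=traj.copy(), sample_step=10)
        df = evaluate_trajectory(est, traj)
        assert (df["accuracy"] == 1.0).all()

    def test_constant_offset_splits_tolerances(self):
        traj = np.zeros((30, 3))
        est = TrajectoryEstimate(angles=traj + 7.0, sample_step=10)
        df = evaluate_trajectory(est, traj)
        assert (df.loc[df.tol == 5.0, "accuracy"] == 0.0).all()
        assert (df.loc[df.tol == 10.0, "accuracy"] == 1.0).all()

    def test_truth_too_short_rejected(self):
        est = TrajectoryEstimate(angles=np.zeros((20, 3)))
        with pytest.raises(ValueError):
            evaluate_trajectory(est, np.zeros((10, 3)))
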