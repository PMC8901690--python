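"""Landmark tracking, rigid co-registration and the circular ROI."""

import numpy as np
import pytest

from ltcstrain.io_frames import FrameSequence
from ltcstrain.registration import (
    LandmarkTrack,
    Landmarks,
    apply_circular_roi,
    compute_frame_transform,
    register_frames,
    track_landmarks,
)
from ltcstrain.synthetic_phantom import make_speckle_field


class TestLandmarks:
    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            Landmarks(apex=(0, 0), annulus_septal=(1, 1), annulus_lateral=(2, 2))

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError):
            Landmarks(apex=(5, 5), annulus_septal=(5, 5), annulus_lateral=(9, 2))


class TestComputeFrameTransform:
    def test_symmetric_geometry(self):
        t = compute_frame_transform(Landmarks((50, 10), (30, 90), (70, 90)))
        assert t.center[0] == pytest.approx(50.0)
        assert t.center[1] == pytest.approx(190.0 / 3.0)
        assert t.angle == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [10.0, -25.0, 90.0])
    def test_rotation_recovered(self, theta):
        """Rotating the landmark set by theta rotates the measured angle."""
        pts = np.array([[50, 10], [30, 90], [70, 90]], float)
        c = pts.mean(axis=0)
        th = np.radians(theta)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = (pts - c) @ R.T + c
        t = compute_frame_transform(Landmarks.from_array(rot))
        assert t.angle == pytest.approx(theta, abs=1e-6)


class TestTrackLandmarks:
    def _seq(self, frames):
        return FrameSequence(frames=np.asarray(frames), frame_interval=0.02)

    def test_identical_frames_landmarks_static(self):
        f = make_speckle_field((160, 160), density=0.15, seed=4)
        seq = self._seq([f, f, f])
        lm = Landmarks((80, 50), (55, 120), (105, 120))
        track = track_landmarks(seq, lm)
        assert np.allclose(track.positions, track.positions[0], atol=1e-6)

    def test_circular_shift_recovered(self):
        f = make_speckle_field((192, 192), density=0.15, seed=4)
        g = np.roll(f, (5, 3), axis=(0, 1))  # +3 in x, +5 in y
        seq = self._seq([f, g])
        lm = Landmarks((96, 60), (70, 150), (122, 150))
        track = track_landmarks(seq, lm)
        moved = track.positions[1] - track.positions[0]
        assert np.allclose(moved, [3.0, 5.0], atol=0.1)

    def test_phantom_truth_tracking(self, phantom_cnr8):
        """Tracked landmarks follow the phantom truth to a couple px RMS
        (the wide, clutter-robust window averages motion over its support,
        which under-tracks the fast-moving apex slightly)."""
        seq, truth = phantom_cnr8
        lm = Landmarks.from_array(truth.landmarks[0])
        track = track_landmarks(seq, lm)
        rms = np.sqrt(np.mean((track.positions - truth.landmarks) ** 2))
        assert rms < 2.5

    def test_tracking_error_shrinks_with_cnr(self, phantom_cnr2, phantom_cnr8):
        """Landmark RMS error does not increase when CNR increases."""
        errs = []
        for seq, truth in (phantom_cnr2, phantom_cnr8):
            track = track_landmarks(seq, Landmarks.from_array(truth.landmarks[0]))
            errs.append(np.sqrt(np.mean((track.positions - truth.landmarks) ** 2)))
        assert errs[1] <= errs[0] + 0.25

    def test_initial_landmark_outside_frame(self):
        f = make_speckle_field((64, 64), density=0.15, seed=4)
        seq = self._seq([f, f])
        with pytest.raises(ValueError):
            track_landmarks(seq, Landmarks((100, 100), (10, 50), (50, 50)))


class TestRegisterFrames:
    def test_identity_transforms_reproduce_crop(self):
        f = make_speckle_field((160, 160), density=0.15, seed=4)
        seq = FrameSequence(frames=np.stack([f, f]), frame_interval=0.02)
        lm = np.array([[80, 40], [60, 120], [100, 120]], float)
        reg = register_frames(seq, LandmarkTrack(positions=np.stack([lm, lm])))
        assert reg.frames.shape[1] % 2 == 1  # odd side
        assert np.allclose(reg.frames[0], reg.frames[1], atol=1e-12)

    def test_translation_cancels(self):
        """A translated frame registers onto the reference frame."""
        f = make_speckle_field((200, 200), density=0.15, diameter=5.0, seed=4)
        g = np.roll(f, (-2, 4), axis=(0, 1))  # +4 in x, -2 in y
        seq = FrameSequence(frames=np.stack([f, g]), frame_interval=0.02)
        lm = np.array([[100, 60], [80, 140], [120, 140]], float)
        track = LandmarkTrack(positions=np.stack([lm, lm + [4.0, -2.0]]))
        reg = register_frames(seq, track)
        side = reg.frames.shape[1]
        inner = slice(side // 4, 3 * side // 4)
        assert np.abs(reg.frames[0][inner, inner] - reg.frames[1][inner, inner]).max() < 1e-3

    def test_rotation_cancels(self):
        from scipy.ndimage import rotate

        f = make_speckle_field((200, 200), density=0.15, diameter=5.0, seed=4)
        g = rotate(f, -15.0, reshape=False, order=3)  # clockwise 15 deg in image coords
        seq = FrameSequence(frames=np.stack([f, np.clip(g, 0, 1)]), frame_interval=0.02)
        lm = np.array([[99.5, 59.5], [79.5, 139.5], [119.5, 139.5]], float)
        c = np.array([99.5, 99.5])
        th = np.radians(15.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lm2 = (lm - c) @ R.T + c
        track = LandmarkTrack(positions=np.stack([lm, lm2]))
        reg = register_frames(seq, track)
        side = reg.frames.shape[1]
        inner = slice(side // 3, 2 * side // 3)
        diff = np.abs(reg.frames[0][inner, inner] - reg.frames[1][inner, inner])
        assert np.median(diff) < 5e-3

    def test_translation_equivariance(self):
        """Shifting frames and seeds by the same integer offset changes nothing."""
        base = make_speckle_field((240, 240), density=0.15, seed=4)
        f = base[20:180, 20:180]
        g = base[13:173, 15:175]  # same content shifted by (+5, +7)
        lm = np.array([[80, 65], [68, 120], [92, 120]], float)
        seq1 = FrameSequence(frames=np.stack([f, f]), frame_interval=0.02)
        seq2 = FrameSequence(frames=np.stack([g, g]), frame_interval=0.02)
        r1 = register_frames(seq1, LandmarkTrack(positions=np.stack([lm, lm])))
        lm2 = lm + [5.0, 7.0]
        r2 = register_frames(seq2, LandmarkTrack(positions=np.stack([lm2, lm2])))
        # spline prefiltering feels the (different) crop boundaries at the
        # 1e-6 level; the registered content itself is identical
        assert np.abs(r1.frames - r2.frames).max() < 1e-5

    def test_track_length_mismatch(self):
        f = make_speckle_field((64, 64), density=0.15, seed=4)
        seq = FrameSequence(frames=np.stack([f, f, f]), frame_interval=0.02)
        lm = np.array([[32, 16], [20, 48], [44, 48]], float)
        with pytest.raises(ValueError):
            register_frames(seq, LandmarkTrack(positions=np.stack([lm, lm])))


class TestApplyCircularRoi:
    def test_disk_of_ones(self):
        img = np.ones((41, 41))
        out = apply_circular_roi(img, (20, 20), 20.0, taper=0.0)
        yy, xx = np.mgrid[0:41, 0:41]
        r = np.hypot(xx - 20, yy - 20)
        assert np.all(out[r <= 20] == 1.0)
        assert np.all(out[r > 20] == 0.0)

    def test_boundary_pixel_retained(self):
        img = np.ones((21, 21))
        out = apply_circular_roi(img, (10, 10), 10.0, taper=0.0)
        assert out[10, 0] == 1.0  # exactly at distance == radius

    def test_mask_never_amplifies(self):
        rng = np.random.default_rng(3)
        img = rng.random((41, 41))
        out = apply_circular_roi(img, (20, 20), 15.0, taper=5.0)
        assert out.sum() <= img.sum()
        assert np.all(out <= img + 1e-12)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            apply_circular_roi(np.ones((9, 9)), (4, 4), 0.0)
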