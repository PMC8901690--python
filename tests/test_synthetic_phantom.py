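"""Phantom generators: determinism, truth consistency, CNR calibration."""

import numpy as np
import pytest

from ltcstrain.ltc_core import StrainRateSeries
from ltcstrain.strain_series import integrate_glsr
from ltcstrain.synthetic_phantom import (
    AffineTruth,
    affine_sequence,
    compute_cnr,
    lv_phantom,
    make_speckle_field,
    sample_speckle_blobs,
)


class TestMakeSpeckleField:
    def test_deterministic(self):
        a = make_speckle_field((64, 64), seed=5)
        b = make_speckle_field((64, 64), seed=5)
        assert np.array_equal(a, b)

    def test_blob_count_scales_exactly_with_density(self):
        b1 = sample_speckle_blobs((64, 64), density=0.05, seed=5)
        b2 = sample_speckle_blobs((64, 64), density=0.10, seed=5)
        assert len(b2.amps) == 2 * len(b1.amps)

    def test_mean_intensity_monotone_in_density(self):
        means = [render_mean(d) for d in (0.02, 0.05, 0.10)]
        assert means[0] < means[1] < means[2]

    def test_normalized_range(self):
        f = make_speckle_field((64, 64), seed=5)
        assert f.min() == 0.0
        assert f.max() == 1.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_speckle_field((64, 64), density=0.0)
        with pytest.raises(ValueError):
            make_speckle_field((64, 64), diameter=0.5)


def render_mean(density):
    from ltcstrain.synthetic_phantom import render_speckle

    return render_speckle(sample_speckle_blobs((64, 64), density=density, seed=5)).mean()


class TestAffineSequence:
    def test_identity_pairs_static(self, speckle_field):
        seq, truth = affine_sequence(speckle_field, AffineTruth(a11=[1.0] * 3, a22=[1.0] * 3), 4)
        assert np.allclose(seq.frames, seq.frames[0])
        assert np.allclose(truth.gls_truth, 0.0)

    def test_compound_gls_truth(self, speckle_field):
        truth_in = AffineTruth(a11=[1.0] * 5, a22=[0.98] * 5)
        _, truth = affine_sequence(speckle_field, truth_in, 6)
        assert truth.gls_truth[-1] == pytest.approx((0.98**5 - 1) * 100.0)

    def test_pure_translation_zero_strain_truth(self, speckle_field):
        truth_in = AffineTruth(a11=[1.0] * 3, a22=[1.0] * 3, t1=[3.0] * 3)
        seq, truth = affine_sequence(speckle_field, truth_in, 4)
        assert np.allclose(truth.gls_truth, 0.0)
        assert not np.allclose(seq.frames[1], seq.frames[0])  # content moved

    def test_runaway_deformation_errors(self, speckle_field):
        with pytest.raises(ValueError, match="outside the frame"):
            affine_sequence(speckle_field, AffineTruth(a11=[1.0] * 40, a22=[1.02] * 40), 41)

    def test_invalid_deformation_gradient(self):
        with pytest.raises(ValueError):
            AffineTruth(a11=[1.0], a22=[-0.5])


class TestLvPhantom:
    def test_waveform_peak_and_endpoints(self, phantom_cnr8):
        _, truth = phantom_cnr8
        assert np.abs(truth.gls_truth).max() == pytest.approx(15.0, abs=0.15)
        assert truth.gls_truth[0] == pytest.approx(0.0, abs=1e-9)
        assert abs(truth.gls_truth[-1]) < 1e-9

    @pytest.mark.parametrize("target", [2.0, 4.0, 8.0])
    def test_cnr_hits_target(self, target):
        from scipy import ndimage

        seq, truth = lv_phantom(cnr=target, seed=6)
        vm = ndimage.binary_erosion(truth.ventricle_masks[0], iterations=2)
        tm = ndimage.binary_erosion(truth.myocardium_masks[0], iterations=2)
        assert compute_cnr(seq.frames[0], vm, tm) == pytest.approx(target, abs=0.5)

    def test_determinism(self):
        a, _ = lv_phantom(cnr=4.0, seed=9)
        b, _ = lv_phantom(cnr=4.0, seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_masks_disjoint(self, phantom_cnr8):
        _, truth = phantom_cnr8
        assert not np.any(truth.ventricle_masks & truth.myocardium_masks)

    def test_boundary_arclength_consistent_with_gls(self, phantom_cnr8):
        _, truth = phantom_cnr8
        L = np.linalg.norm(np.diff(truth.boundary, axis=1), axis=2).sum(axis=1)
        arc_gls = (L - L[0]) / L[0] * 100.0
        assert np.abs(arc_gls - truth.gls_truth).max() < 0.2

    def test_rate_truth_integrates_to_gls_truth(self, phantom_cnr8):
        seq, truth = phantom_cnr8
        rates = StrainRateSeries(
            times=(np.arange(len(truth.glsr_truth)) + 0.5) * seq.frame_interval,
            glsr=truth.glsr_truth,
        )
        series = integrate_glsr(rates, seq.frame_interval)
        assert np.abs(series.gls - truth.gls_truth).max() < 0.1

    def test_rejects_out_of_range_peak(self):
        with pytest.raises(ValueError):
            lv_phantom(peak_strain=5.0)
        with pytest.raises(ValueError):
            lv_phantom(n_frames=8)


class TestComputeCnr:
    def test_two_region_arithmetic(self):
        """mu_V=20, mu_T=60, sigma_V=3, sigma_T=4 -> CNR = 40/5 = 8."""
        v = np.array([17.0, 23.0, 17.0, 23.0])  # mean 20, std 3
        t = np.array([56.0, 64.0, 56.0, 64.0])  # mean 60, std 4
        img = np.concatenate([v, t]).reshape(2, 4)
        vmask = np.zeros((2, 4), bool)
        vmask[0] = True
        tmask = ~vmask
        assert compute_cnr(img, vmask, tmask) == pytest.approx(8.0)

    def test_identical_regions_zero(self):
        rng = np.random.default_rng(0)
        img = rng.random((10, 10))
        img[5:] = img[:5]
        vmask = np.zeros((10, 10), bool)
        vmask[:5] = True
        assert compute_cnr(img, vmask, ~vmask) == pytest.approx(0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.random((10, 10)) + 0.5
        vmask = np.zeros((10, 10), bool)
        vmask[:5] = True
        c1 = compute_cnr(img, vmask, ~vmask)
        c2 = compute_cnr(3.7 * img, vmask, ~vmask)
        assert c1 == pytest.approx(c2)

    def test_constant_regions_error(self):
        img = np.ones((4, 4))
        vmask = np.zeros((4, 4), bool)
        vmask[:2] = True
        with pytest.raises(ValueError):
            compute_cnr(img, vmask, ~vmask)
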