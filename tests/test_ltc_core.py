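"""Spectral kernel: FT magnitude, log resampling, correlation, strain."""

import numpy as np
import pytest

from ltcstrain import ltc_core
from ltcstrain.ltc_core import (
    LogSpectralImage,
    dynamic_phase_filter,
    ensemble_correlate,
    ft_magnitude,
    log_resample,
    pairwise_glsr,
    pairwise_strain,
    shift_to_strain_rate,
    spectral_correlate,
    subpixel_peak,
)


class TestFtMagnitude:
    def test_constant_image_is_pure_dc(self):
        spec = ft_magnitude(np.ones((65, 65)), window=False, pad=1)
        mag = spec.magnitude
        c = mag.shape[0] // 2
        assert mag[c, c] > 0
        off_dc = mag.copy()
        off_dc[c, c] = 0.0
        assert off_dc.max() < 1e-9 * mag[c, c]

    def test_translation_invariance_of_magnitude(self, speckle_field):
        f = speckle_field[:129, :129]
        a = ft_magnitude(f, window=False, pad=1).magnitude
        b = ft_magnitude(np.roll(f, (7, 11), axis=(0, 1)), window=False, pad=1).magnitude
        assert np.abs(a - b).max() < 1e-9 * a.max()

    def test_point_reflection_symmetry(self, speckle_field):
        mag = ft_magnitude(speckle_field).magnitude
        assert np.abs(mag - mag[::-1, ::-1]).max() < 1e-9 * mag.max()

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            ft_magnitude(np.zeros((32, 64)))


class TestLogResample:
    def test_constant_magnitude_gives_constant_log_images(self):
        spec = ft_magnitude(np.zeros((65, 65)), window=False)
        spec.values = np.full_like(spec.values, 3.0)
        quads = log_resample(spec, n_samples=48)
        for q in quads:
            assert np.allclose(q.values, 3.0)

    def test_quadrant_symmetry_for_real_input(self, speckle_field):
        quads = log_resample(ft_magnitude(speckle_field))
        assert np.allclose(quads[0].values, quads[2].values, atol=1e-9)
        assert np.allclose(quads[1].values, quads[3].values, atol=1e-9)

    def test_isotropic_rescale_becomes_uniform_log_shift(self):
        """An analytically rescaled Gaussian spectrum shifts by ln(s)/step."""
        n = 257
        ax = np.arange(n) - n // 2
        rr2 = ax[:, None] ** 2 + ax[None, :] ** 2
        s = 1.25
        spec_a = ft_magnitude(np.zeros((n, n)), pad=1)
        spec_b = ft_magnitude(np.zeros((n, n)), pad=1)
        spec_a.values = np.exp(-rr2 / (2 * 30.0**2)) + 0j
        spec_b.values = np.exp(-rr2 * s**2 / (2 * 30.0**2)) + 0j  # B(u) = A(s*u)
        qa = log_resample(spec_a, n_samples=128)
        qb = log_resample(spec_b, n_samples=128)
        step = qa[0].log_step
        shift = np.log(s) / step
        a, b = qa[0].values, qb[0].values
        # B's log image equals A's shifted left by ln(s)/step samples;
        # undo the shift and compare away from the fill-in margin
        from scipy.ndimage import shift as ndshift

        b_back = ndshift(b, (shift, shift), order=1)
        margin = int(np.ceil(shift)) + 2
        interior = slice(margin, 100)
        num = np.abs(a[interior, interior] - b_back[interior, interior]).max()
        assert num < 0.01 * a.max()

    def test_rejects_oversampling_beyond_nyquist(self, speckle_field):
        spec = ft_magnitude(speckle_field[:65, :65])
        with pytest.raises(ValueError, match="Nyquist"):
            log_resample(spec, n_samples=10_000)

    def test_rejects_tiny_sample_count(self, speckle_field):
        spec = ft_magnitude(speckle_field[:65, :65])
        with pytest.raises(ValueError):
            log_resample(spec, n_samples=8)


class TestDynamicPhaseFilter:
    def test_identity_limit(self):
        rng = np.random.default_rng(0)
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, (32, 32)))
        out = dynamic_phase_filter(phases, np.inf)
        assert np.allclose(out, phases)

    def test_output_bounded_by_envelope(self):
        rng = np.random.default_rng(1)
        cs = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        out = dynamic_phase_filter(cs, effective_diameter=16.0)
        fy = np.fft.fftfreq(32) * 32
        rho2 = fy[:, None] ** 2 + fy[None, :] ** 2
        env = np.exp(-rho2 / (2 * 4.0**2))
        assert np.all(np.abs(out) <= env + 1e-12)

    def test_peak_location_unchanged_on_clean_shift(self, speckle_field):
        a = speckle_field[:129, :129]
        b = np.roll(a, (2, 5), axis=(0, 1))
        cp_plain = spectral_correlate(a, b, phase_filter=True, envelope_diameter=np.inf)
        cp_filt = spectral_correlate(a, b, phase_filter=True, envelope_diameter=64.0)
        assert abs(cp_plain.peak_shift[0] - cp_filt.peak_shift[0]) < 0.05
        assert abs(cp_plain.peak_shift[1] - cp_filt.peak_shift[1]) < 0.05

    def test_all_zero_spectrum_errors(self):
        with pytest.raises(ValueError):
            dynamic_phase_filter(np.zeros((8, 8), complex), 4.0)


class TestSubpixelPeak:
    def test_delta_at_center(self):
        p = np.zeros((33, 33))
        p[16, 16] = 1.0
        assert subpixel_peak(p) == (0.0, 0.0)

    def test_gaussian_offset_recovery(self):
        yy, xx = np.mgrid[0:41, 0:41]
        p = np.exp(-((xx - 21.3) ** 2 + (yy - 19.6) ** 2) / (2 * 2.0**2))
        dx, dy = subpixel_peak(p)
        assert abs(dx - 1.3) < 0.02
        assert abs(dy - (-0.4)) < 0.02

    def test_flat_plane_errors(self):
        with pytest.raises(ValueError):
            subpixel_peak(np.ones((9, 9)))

    def test_tied_maxima_error(self):
        p = np.zeros((9, 9))
        p[3, 3] = p[5, 5] = 1.0
        with pytest.raises(ValueError, match="tied"):
            subpixel_peak(p)

    def test_border_peak_errors(self):
        p = np.zeros((9, 9))
        p[0, 4] = 1.0
        with pytest.raises(ValueError, match="border"):
            subpixel_peak(p)


class TestEnsembleCorrelate:
    def test_identical_pair_zero_shift(self, speckle_field):
        quads = log_resample(ft_magnitude(speckle_field))
        cp = ensemble_correlate([(q, q) for q in quads])
        assert abs(cp.peak_shift[0]) < 1e-6
        assert abs(cp.peak_shift[1]) < 1e-6

    def test_constructed_log_shift_recovered(self, speckle_field):
        quads = log_resample(ft_magnitude(speckle_field))
        shifted = [
            LogSpectralImage(values=np.roll(q.values, (2, 2), axis=(0, 1)),
                             log_step=q.log_step, quadrant_id=q.quadrant_id)
            for q in quads
        ]
        cp = ensemble_correlate(list(zip(quads, shifted)))
        assert abs(cp.peak_shift[0] - 2.0) < 0.1
        assert abs(cp.peak_shift[1] - 2.0) < 0.1

    def test_size_mismatch_errors(self, speckle_field):
        quads = log_resample(ft_magnitude(speckle_field))
        small = log_resample(ft_magnitude(speckle_field[:129, :129]))
        with pytest.raises(ValueError):
            ensemble_correlate([(quads[0], small[0])])


class TestShiftToStrainRate:
    def test_zero_shift_zero_rate(self):
        assert shift_to_strain_rate(0.0, 1.0, 0.02) == 0.0

    def test_two_percent_shortening(self):
        rate = shift_to_strain_rate(np.log(0.98), 1.0, 0.02)
        assert rate == pytest.approx(-1.0, abs=1e-12)

    def test_rejects_bad_interval(self):
        with pytest.raises(ValueError):
            shift_to_strain_rate(0.0, 1.0, 0.0)


class TestPairwiseStrain:
    @pytest.mark.parametrize("a22", [0.96, 0.98, 1.00, 1.02, 1.04])
    def test_scale_recovery(self, scaled_pair_factory, a22):
        fa, fb, _ = scaled_pair_factory(a22)
        _, _, eps, _ = pairwise_strain(fa, fb)
        assert abs(eps - (a22 - 1.0)) < 0.004

    def test_translation_invariance(self, scaled_pair_factory):
        fa, fb, _ = scaled_pair_factory(0.98)
        _, _, e0, _ = pairwise_strain(fa, fb)
        _, _, e1, _ = pairwise_strain(np.roll(fa, (3, 5), axis=(0, 1)),
                                      np.roll(fb, (3, 5), axis=(0, 1)))
        assert abs(e1 - e0) < 0.002

    def test_horizontal_vertical_decoupling(self, scaled_pair_factory):
        fa, fb, _ = scaled_pair_factory(1.00, a11=1.03)
        dx_p, _, eps, _ = pairwise_strain(fa, fb)
        assert abs(eps) < 0.005
        assert dx_p == pytest.approx(np.log(1.03), abs=0.005)

    def test_phantom_pair_strain(self, scaled_pair_factory):
        fa, fb, truth = scaled_pair_factory(1.03)
        _, _, eps, _ = pairwise_strain(fa, fb)
        assert eps == pytest.approx(truth.pair_strain[0], abs=0.003)


class TestPairwiseGlsr:
    def test_static_sequence_near_zero(self, speckle_field):
        rng = np.random.default_rng(7)
        frame = np.clip(speckle_field[:161, :161] + 0.02 * rng.standard_normal((161, 161)), 0, 1)

        class Reg:
            frames = np.stack([frame] * 4)
            frame_interval = 0.02

        rates = pairwise_glsr(Reg())
        assert np.nanmax(np.abs(rates.glsr)) < 1e-3

    def test_constant_scale_sequence(self):
        """Constant per-pair shortening of 2% at 50 FPS reads -1.0 1/s."""
        from ltcstrain.synthetic_phantom import AffineTruth, affine_sequence, sample_speckle_blobs

        blobs = sample_speckle_blobs((257, 257), density=0.08, diameter=3.0, seed=1)
        seq, _ = affine_sequence(blobs, AffineTruth(a11=[0.98] * 3, a22=[0.98] * 3),
                                 4, frame_interval=0.02)

        class Reg:
            frames = seq.frames
            frame_interval = 0.02

        rates = pairwise_glsr(Reg())
        assert np.allclose(rates.glsr, -1.0, rtol=0.10)

    def test_times_are_pair_midpoints(self, speckle_field):
        class Reg:
            frames = np.stack([speckle_field[:129, :129]] * 3)
            frame_interval = 0.04

        rates = pairwise_glsr(Reg())
        assert np.allclose(rates.times, [0.02, 0.06])


def test_estimate_envelope_diameter_tracks_feature_size():
    """Coarser textures give a narrower spectral envelope estimate."""
    from ltcstrain.synthetic_phantom import make_speckle_field

    fine = make_speckle_field((129, 129), diameter=2.0, seed=3)
    coarse = make_speckle_field((129, 129), diameter=6.0, seed=3)
    assert ltc_core.estimate_envelope_diameter(coarse) < ltc_core.estimate_envelope_diameter(fine)
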