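import numpy as np
import pytest

from simqc.hyperstack import DimensionError, RawSIMStack, ReconStack
from simqc.reconchecks import (FourierOptions, apply_cutoff, fourier_plots,
                               mcnr_lut, modulation_contrast_map,
                               reconstructed_intensity_histogram,
                               spherical_aberration_mismatch)
from simqc.rawchecks import mcnr
from simqc.synth import SimScenario, generate_bead_field, generate_raw_sim, \
    generate_recon_like, pseudo_reconstruct


def recon_from(arr, **kw):
    return ReconStack(np.asarray(arr, dtype=np.float32)[None, None], **kw)


class TestReconstructedIntensityHistogram:
    def test_constructed_mmr_oracle(self, recon_like):
        rih = reconstructed_intensity_histogram(recon_like)
        assert rih.mmr[0] == pytest.approx(2.0, abs=0.02)
        assert rih.min_star[0] == pytest.approx(-50.0, abs=0.5)
        assert rih.max_star[0] == pytest.approx(100.0, abs=0.5)

    def test_symmetric_tails_give_unit_ratio(self):
        vol = np.zeros((10, 100, 100))
        vol.flat[:200] = 50.0
        vol.flat[200:400] = -50.0
        rih = reconstructed_intensity_histogram(recon_from(vol))
        assert rih.mmr[0] == pytest.approx(1.0, abs=0.02)

    def test_minimum_tail_pixel_count(self):
        vol = np.random.default_rng(0).normal(size=(10, 100, 100))
        rih = reconstructed_intensity_histogram(recon_from(vol))
        # 0.05% of 1e5 = 50 < floor of 100 pixels
        assert rih.n_min[0] == 100 and rih.n_max[0] == 100

    def test_mmr_invariant_under_affine_shift(self, recon_like):
        rih1 = reconstructed_intensity_histogram(recon_like)
        shifted = recon_from(recon_like.data[0, 0] + 37.5)
        rih2 = reconstructed_intensity_histogram(shifted)
        assert rih2.mmr[0] == pytest.approx(rih1.mmr[0], rel=1e-9)
        assert rih2.mode[0] == pytest.approx(rih1.mode[0] + 37.5, rel=1e-6)

    def test_clipped_data_yields_undefined_sentinel(self):
        vol = np.full((4, 50, 50), 7.0)   # hard-clipped floor: mode == Min*
        with pytest.warns(UserWarning, match="MMR undefined"):
            rih = reconstructed_intensity_histogram(recon_from(vol))
        assert np.isnan(rih.mmr[0])

    def test_trimmed_flag_warns(self, recon_like):
        trimmed = ReconStack(recon_like.data, full_range=False)
        with pytest.warns(UserWarning, match="full"):
            reconstructed_intensity_histogram(trimmed)


class TestSphericalAberrationMismatch:
    def test_z_invariant_stack_has_zero_zmv(self):
        rng = np.random.default_rng(1)
        slice_ = rng.normal(10, 3, size=(40, 40))
        vol = np.repeat(slice_[None], 6, axis=0)
        sam = spherical_aberration_mismatch(recon_from(vol))
        assert sam.zmv[0] == pytest.approx(0.0, abs=1e-9)

    def test_constructed_ratio(self):
        # minima per z with std 5, features with mean 100 -> ZMV = 0.05
        z = 8
        vol = np.zeros((z, 50, 50))
        minima = np.array([-10., 0., -10., 0., -10., 0., -10., 0.])  # std = 5
        for i in range(z):
            vol[i, 0, 0] = minima[i]
            vol[i, 10:20, 10:20] = 100.0
        sam = spherical_aberration_mismatch(recon_from(vol))
        assert sam.feature_mean[0] == pytest.approx(100.0)
        assert sam.zmv[0] == pytest.approx(0.05, rel=1e-9)

    def test_zmv_invariant_under_positive_scaling(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(0, 1, size=(6, 40, 40))
        vol[:, 5:15, 5:15] += 60.0
        z1 = spherical_aberration_mismatch(recon_from(vol)).zmv[0]
        z2 = spherical_aberration_mismatch(recon_from(vol * 13.0)).zmv[0]
        assert z2 == pytest.approx(z1, rel=1e-3)

    def test_defocused_pattern_raises_zmv(self):
        """An axially offset illumination focus produces sign-flipping
        demodulated output, deepening slice minima relative to features."""
        for seed in (0, 1, 2):
            density = generate_bead_field((13, 48, 48), 150, psf_sigma_z=1.5,
                                          seed=seed, z_layer=6)
            zmvs = []
            for dz in (0.0, 0.25):
                sc = SimScenario(shape=(13, 48, 48), m=0.9,
                                 focus_offset_um=dz, seed=seed)
                raw, truth = generate_raw_sim(density, sc)
                rec = pseudo_reconstruct(raw, truth, upscale=False)
                zmvs.append(spherical_aberration_mismatch(rec).zmv[0])
            assert zmvs[1] > zmvs[0], seed

    def test_too_few_slices_rejected(self):
        with pytest.raises(DimensionError):
            spherical_aberration_mismatch(recon_from(np.zeros((2, 8, 8))))


class TestFourierPlots:
    def test_centered_impulse_flat_radial_profile(self):
        vol = np.zeros((3, 64, 64))
        vol[:, 32, 32] = 100.0
        fps = fourier_plots(recon_from(vol),
                            FourierOptions(cutoff=None))
        prof = fps.ftr[0]
        assert prof[1:] == pytest.approx(prof[1], rel=1e-6)

    def test_resolution_ring_radius_formula(self):
        vol = np.zeros((3, 512, 512))
        vol[:, 200:210, 200:210] = 5.0
        rec = recon_from(vol, pixel_xy=0.04)
        fps = fourier_plots(rec, FourierOptions(cutoff=None))
        assert fps.ring_radii_px[0.1] == pytest.approx(204.8)

    def test_band_limited_profile_drops_at_cutoff_frequency(self):
        # image with power concentrated below radius r0 in frequency space
        n = 64
        r0 = 10
        rng = np.random.default_rng(3)
        spec = np.zeros((n, n), dtype=complex)
        yy, xx = np.ogrid[0:n, 0:n]
        inside = (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= r0 ** 2
        spec[inside] = rng.normal(size=inside.sum()) * 50
        img = np.fft.ifft2(np.fft.ifftshift(spec)).real
        vol = np.repeat(img[None], 3, axis=0)
        fps = fourier_plots(recon_from(vol), FourierOptions(cutoff=None))
        prof = fps.ftr[0]
        assert prof[:r0 - 1].mean() > 10 * prof[r0 + 3:].mean()

    def test_isotropic_reslice_factor(self):
        vol = np.random.default_rng(4).normal(size=(8, 32, 32)) + 10
        rec = recon_from(vol, pixel_xy=0.04, pixel_z=0.125)
        fps = fourier_plots(rec, FourierOptions(cutoff=None))
        assert fps.fto.shape[1] == round(8 * 3.125)

    def test_white_noise_radial_profile_flat(self):
        profs = []
        for seed in range(5):
            vol = np.random.default_rng(seed).normal(size=(3, 64, 64))
            fps = fourier_plots(recon_from(vol), FourierOptions(cutoff=None))
            profs.append(fps.ftr[0])
        mean_prof = np.mean(profs, axis=0)[4:]   # away from DC bins
        rel = mean_prof / np.median(mean_prof) - 1
        # flat to within 5% RMS; individual small-radius annuli carry few
        # independent samples, so only guard their worst case loosely
        assert np.sqrt(np.mean(rel ** 2)) < 0.05
        assert np.abs(rel).max() < 0.2

    def test_auto_cutoff_zero_fraction_matches_below_mode_fraction(self,
                                                                   recon_like):
        vol = recon_like.data[0, 0]
        from simqc.utils import histogram_mode

        mode = histogram_mode(vol)
        cut = apply_cutoff(vol, "auto")
        assert (cut == 0).mean() == pytest.approx((vol <= mode).mean())

    def test_gamma_scaling_of_displayed_spectrum(self):
        vol = np.full((3, 32, 32), 4.0)
        fps = fourier_plots(recon_from(vol), FourierOptions(cutoff=None))
        # DC amplitude = 4 * 32 * 32; displayed value is its 0.2 power
        assert fps.ftl[0, 1, 16, 16] == pytest.approx((4 * 32 * 32) ** 0.2,
                                                      rel=1e-6)


class TestModulationContrastMap:
    @pytest.fixture()
    def pair(self, clean_raw):
        raw, truth, _ = clean_raw
        rec = pseudo_reconstruct(raw, truth)
        res = mcnr(RawSIMStack(np.round(raw.data), bit_depth=15), zw=1)
        raw15 = RawSIMStack(raw.data, bit_depth=15, pixel_xy=raw.pixel_xy,
                            pixel_z=raw.pixel_z)
        return raw15, rec, res

    def test_zero_intensity_renders_black(self, pair):
        raw, rec, res = pair
        dark = ReconStack(np.zeros_like(rec.data), pixel_xy=rec.pixel_xy)
        mcm = modulation_contrast_map(dark, res, raw)
        assert np.all(mcm.rgb == 0)

    def test_saturated_raw_voxel_marks_green(self, pair):
        raw, rec, res = pair
        data = raw.data.copy()
        data[0, 1, 4, 2, 0, 20, 30] = raw.saturation_level
        sat_raw = RawSIMStack(data, bit_depth=raw.bit_depth)
        mcm = modulation_contrast_map(rec, res, sat_raw)
        assert mcm.saturation_mask[0, 4, 40, 60]
        r, g, b = mcm.rgb[0, 4, 40, 60]
        if rec.data[0, 0, 4, 40, 60] > 0:
            assert g > 0 and r == 0 and b == 0

    def test_uniform_mcnr_uniform_intensity_gives_uniform_colour(self):
        raw = RawSIMStack(np.ones((1, 3, 3, 5, 1, 8, 8)), bit_depth=15)
        rec = ReconStack(np.full((1, 1, 3, 16, 16), 7.0))
        from simqc.rawchecks import McnrResult

        res = McnrResult(mcnr_map=np.full((1, 3, 8, 8), 12.0),
                         feature_mean_mcnr=np.array([12.0]),
                         wiener_suggestion=np.array([0.17 / 144]),
                         z_window=1,
                         order1_power=np.zeros((1, 3, 8, 8)),
                         order2_power=np.zeros((1, 3, 8, 8)),
                         noise_sigma=np.ones((1, 3)))
        mcm = modulation_contrast_map(rec, res, raw)
        expected = mcnr_lut()[int(12.0 / 24.0 * 256)]
        flat = mcm.rgb[0].reshape(-1, 3)
        assert np.allclose(flat, expected, atol=1e-9)

    def test_shape_mismatch_rejected(self, pair):
        raw, rec, res = pair
        bad = ReconStack(rec.data[:, :, :, :-2, :])
        with pytest.raises(DimensionError):
            modulation_contrast_map(bad, res, raw)
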