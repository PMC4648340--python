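import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import simqc
from simqc.hyperstack import DimensionError, RawSIMStack, SimqcError
from simqc.rawchecks import (anscombe, channel_intensity_profile, mcnr,
                             motion_illumination_variation,
                             phase_order_indices, raw_fourier_projection,
                             wiener_suggestion)
from simqc.synth import SimScenario, generate_raw_sim


def uniform_raw(value=50.0, shape=(9, 32, 32), **scenario_kw):
    sc = SimScenario(shape=shape, m=0.0, seed=0, **scenario_kw)
    raw, _ = generate_raw_sim(np.full(shape, value), sc)
    return raw


class TestChannelIntensityProfile:
    def test_constant_stack_all_statistics_zero(self):
        cip = channel_intensity_profile(uniform_raw())
        for stat in (cip.tiv, cip.decay, cip.max_angle_diff, cip.flicker):
            assert stat == pytest.approx(0.0, abs=1e-9)
        assert cip.n_window_images == 135

    def test_tiv_of_linear_ramp_over_window(self):
        # plane means ramp 1.0 -> 0.8 across the 9-z window: TIV = 20%
        raw = uniform_raw(shape=(9, 32, 32))
        data = raw.data.astype(float)
        ramp = np.linspace(1.0, 0.8, 9)
        data *= ramp[None, None, :, None, None, None, None]
        cip = channel_intensity_profile(RawSIMStack(data))
        assert cip.tiv[0] == pytest.approx(20.0, abs=0.1)

    def test_angle_gain_imbalance(self):
        raw = uniform_raw(angle_gains=(1.0, 1.0, 0.8))
        cip = channel_intensity_profile(raw)
        assert cip.max_angle_diff[0] == pytest.approx(20.0, abs=1e-6)
        assert cip.decay[0] == pytest.approx(0.0, abs=1e-6)

    def test_bleaching_decay_estimate(self):
        sc = SimScenario(shape=(9, 16, 16), m=0.0, bleach_per_plane=0.002,
                         seed=0)
        raw, _ = generate_raw_sim(np.full(sc.shape, 50.0), sc)
        cip = channel_intensity_profile(raw)
        # 45 planes per angle: loss first -> last within an angle = 0.998^44
        expected = 100.0 * (1.0 - 0.998 ** 44)
        assert cip.decay[0] == pytest.approx(expected, rel=0.01)
        assert cip.tiv[0] > 0

    def test_statistics_invariant_under_global_scaling(self):
        sc = SimScenario(shape=(9, 24, 24), m=0.3, angle_gains=(1.0, 0.9, 1.1),
                         bleach_per_plane=0.001, flicker=0.01, seed=5)
        raw, _ = generate_raw_sim(np.full(sc.shape, 40.0), sc)
        cip1 = channel_intensity_profile(raw)
        cip2 = channel_intensity_profile(RawSIMStack(raw.data * 7.5))
        for a, b in ((cip1.tiv, cip2.tiv),
                     (cip1.flicker, cip2.flicker),
                     (cip1.max_angle_diff, cip2.max_angle_diff)):
            assert a == pytest.approx(b, rel=1e-9)

    def test_short_stack_window_truncated(self):
        cip = channel_intensity_profile(uniform_raw(shape=(3, 16, 16)))
        assert cip.window == (0, 3)


class TestRawFourierProjection:
    def test_centered_impulse_gives_degenerate_flat_output(self):
        data = np.zeros((1, 1, 1, 3, 1, 32, 32))
        data[..., 16, 16] = 1000.0
        out = raw_fourier_projection(RawSIMStack(data))
        # flat spectrum: nothing to contrast after center fill and rescale
        assert out.shape == (1, 32, 32)
        assert np.all(out == 0)

    def test_stripes_give_symmetric_first_order_spots(self):
        sc = SimScenario(shape=(3, 64, 64), m=0.8, k=8 / 64, angles_deg=(0,),
                         n_angles=1, axial_period_um=100.0, seed=0)
        raw, _ = generate_raw_sim(np.full(sc.shape, 100.0), sc)
        out = raw_fourier_projection(raw)[0]
        # spots at (center, center +- 8); exclude the filled disc
        assert out[32, 40] > 0.9
        assert out[32, 24] > 0.9

    def test_three_angle_acquisition_shows_six_spots(self, clean_raw):
        raw, truth, sc = clean_raw
        out = raw_fourier_projection(raw)[0]
        n = out.shape[0]
        c = n // 2
        for th in truth.angles_deg:
            dx = sc.k * n * np.cos(np.deg2rad(th))
            dy = sc.k * n * np.sin(np.deg2rad(th))
            for sign in (1, -1):
                iy, ix = int(round(c + sign * dy)), int(round(c + sign * dx))
                spot = out[iy - 1:iy + 2, ix - 1:ix + 2].max()
                assert spot > 0.7, (th, sign, spot)


class TestMotionIlluminationVariation:
    def test_identical_angles_give_grey(self):
        raw = uniform_raw()
        miv = motion_illumination_variation(raw)
        rgb = miv.rgb[0, 4]
        assert np.allclose(rgb[..., 0], rgb[..., 1], atol=1e-9)
        assert np.allclose(rgb[..., 1], rgb[..., 2], atol=1e-9)

    def test_uniform_gain_removed_by_normalization(self):
        raw = uniform_raw(angle_gains=(2.0, 1.0, 1.0))
        miv = motion_illumination_variation(raw)
        rgb = miv.rgb[0, 4]
        assert np.allclose(rgb[..., 0], rgb[..., 1], atol=1e-9)
        assert np.allclose(rgb[..., 1], rgb[..., 2], atol=1e-9)

    def test_angle1_only_signal_appears_cyan(self):
        data = np.ones((1, 3, 1, 5, 1, 16, 16))
        data[0, 0, 0, :, 0, 8, 8] = 50.0     # feature only in angle 1 (cyan)
        miv = motion_illumination_variation(RawSIMStack(data))
        r, g, b = miv.rgb[0, 0, 8, 8]
        assert r < g
        assert g == pytest.approx(b, abs=1e-9)

    def test_rgb_channels_within_unit_range(self, noisy_raw):
        miv = motion_illumination_variation(noisy_raw[0])
        assert miv.rgb.min() >= 0.0 and miv.rgb.max() <= 1.0

    def test_two_angles_rejected(self):
        data = np.ones((1, 2, 1, 5, 1, 8, 8))
        with pytest.raises(DimensionError):
            motion_illumination_variation(RawSIMStack(data))


class TestAnscombe:
    def test_closed_form_values(self):
        assert anscombe(0.0) == pytest.approx(2 * np.sqrt(3 / 8))
        assert anscombe(1.0) == pytest.approx(2 * np.sqrt(11 / 8))

    def test_negative_input_rejected(self):
        with pytest.raises(SimqcError):
            anscombe(-1.0)

    def test_variance_stabilization_of_poisson_noise(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(100.0, size=100_000)
        assert anscombe(x).var() == pytest.approx(1.0, rel=0.1)


class TestPhaseOrderIndices:
    @pytest.mark.parametrize("p,zw,expected", [
        (5, 1, (15, 4, 7)),     # 5 phases * 3 z-sections = 15
        (5, 0, (5, 2, 3)),
        (3, 1, (9, 4, 7)),
    ])
    def test_known_indices(self, p, zw, expected):
        assert phase_order_indices(p, zw) == expected

    # second order omitted for 3 phases, where it aliases onto the first
    @pytest.mark.parametrize("p,order", [(3, 1), (5, 1), (5, 2), (7, 1),
                                         (7, 2)])
    @pytest.mark.parametrize("zw", [0, 1, 2])
    def test_matches_brute_force_dft_argmax(self, p, zw, order):
        """A pure single-order phase series has its DFT power maximum exactly
        at the predicted plane index."""
        l_ft, idx1, idx2 = phase_order_indices(p, zw)
        n = np.arange(l_ft)
        series = np.cos(2 * np.pi * order * (n % p) / p + 0.3)
        power = np.abs(np.fft.fft(series)) ** 2
        brute = int(np.argmax(power[1:l_ft // 2 + 1])) + 1   # 0-based k > 0
        predicted = (idx1, idx2)[order - 1] - 1              # to 0-based
        assert brute == predicted

    def test_invalid_arguments_rejected(self):
        with pytest.raises(DimensionError):
            phase_order_indices(2, 1)
        with pytest.raises(DimensionError):
            phase_order_indices(5, -1)


class TestMcnr:
    def test_constant_phase_series_has_no_order_power(self):
        raw = uniform_raw(value=100.0, shape=(5, 24, 24))
        with pytest.warns(UserWarning):
            res = mcnr(raw)
        assert res.order1_power.max() == pytest.approx(0.0, abs=1e-9)
        assert res.order2_power.max() == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_modulation_depth(self, bead_density):
        vals = []
        for m in (0.2, 0.5, 0.9):
            sc = SimScenario(shape=(9, 64, 64), m=m, poisson=True,
                             read_noise=2.0, seed=11)
            raw, _ = generate_raw_sim(bead_density, sc)
            vals.append(mcnr(raw).feature_mean_mcnr[0])
        assert vals[0] < vals[1] < vals[2]

    def test_no_modulation_sits_at_noise_baseline(self, bead_density):
        lows, highs = [], []
        for seed in (3, 4, 5):
            for m, acc in ((0.0, lows), (0.9, highs)):
                sc = SimScenario(shape=(9, 64, 64), m=m, poisson=True,
                                 read_noise=2.0, seed=seed)
                raw, _ = generate_raw_sim(bead_density, sc)
                acc.append(mcnr(raw).feature_mean_mcnr[0])
        # pure-noise order amplitudes normalized by their own spread give a
        # baseline near 3, independent of the sample
        assert max(lows) < 0.6 * min(highs)
        assert max(lows) < 4.0

    def test_map_stable_under_global_gain(self, bead_density):
        sc = SimScenario(shape=(9, 64, 64), m=0.6, poisson=True,
                         read_noise=1.0, seed=2)
        raw, _ = generate_raw_sim(50.0 + bead_density, sc)  # lambda >= 50
        fm1 = mcnr(raw).feature_mean_mcnr[0]
        fm2 = mcnr(RawSIMStack(raw.data * 10.0)).feature_mean_mcnr[0]
        assert abs(fm2 - fm1) / fm1 <= 0.05

    def test_wiener_follows_feature_mean(self, noisy_raw):
        res = mcnr(noisy_raw[0])
        assert res.wiener_suggestion[0] == pytest.approx(
            0.17 / res.feature_mean_mcnr[0] ** 2)


class TestWienerSuggestion:
    def test_reference_points(self):
        assert wiener_suggestion(1.0) == pytest.approx(0.17)
        assert wiener_suggestion(2.0) == pytest.approx(0.0425)

    def test_strictly_decreasing_towards_zero(self):
        values = [wiener_suggestion(m) for m in (1.0, 2.0, 5.0, 20.0, 1e6)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 1e-12

    def test_nonpositive_input_returns_none(self):
        with pytest.warns(UserWarning):
            assert wiener_suggestion(0.0) is None

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_positive_for_positive_mcnr(self, fm):
        assert wiener_suggestion(fm) > 0
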