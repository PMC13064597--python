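"""Phantom simulator: ground-truth rasterization, calibrated speckle
statistics, camera noise moments, determinism."""

import numpy as np
import pytest

import specklight as sl
from specklight.phantom import _speckle_series


def _spec(**kw):
    base = dict(height=16, width=16, n_frames=100, fps=100.0, exposure_us=9500.0)
    base.update(kw)
    return sl.PhantomSpec(**base)


class TestTauMap:
    def test_no_lesion_uniform(self):
        gt = sl.make_phantom_tau_map(_spec(background_tau_c=0.4))
        assert np.all(gt.tau_c_map == 0.4)
        assert not gt.lesion_mask.any()

    def test_single_lesion_two_levels(self):
        les = sl.Lesion(8, 8, 3, 4, tau_c=0.67)
        gt = sl.make_phantom_tau_map(_spec(background_tau_c=0.39, lesions=(les,)))
        assert set(np.unique(gt.tau_c_map)) == {0.39, 0.67}
        assert np.all((gt.tau_c_map == 0.67) == gt.lesion_mask)

    def test_overlapping_lesions_last_wins(self):
        a = sl.Lesion(8, 8, 3, 3, tau_c=0.5)
        b = sl.Lesion(9, 9, 3, 3, tau_c=0.8)
        gt = sl.make_phantom_tau_map(_spec(lesions=(a, b)))
        overlap = a.mask(16, 16) & b.mask(16, 16)
        assert overlap.any()
        assert np.all(gt.tau_c_map[overlap] == 0.8)

    def test_lesion_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _spec(lesions=(sl.Lesion(2, 8, 5, 3, tau_c=0.5),))

    def test_exposure_cannot_exceed_frame_period(self):
        with pytest.raises(ValueError, match="exposure"):
            _spec(fps=200.0, exposure_us=9500.0)

    def test_beta_validated(self):
        with pytest.raises(ValueError, match="beta"):
            _spec(beta=1.5)


class TestPixelSeries:
    def test_static_series_has_zero_variance(self):
        s = sl.simulate_pixel_intensity("static", 500, 100.0, seed=0)
        assert np.all(s == s[0])  # frozen speckle: zero temporal variance
        assert s[0] > 0

    def test_invalid_tau_rejected(self):
        for bad in (0.0, -1.0, np.nan):
            with pytest.raises(ValueError):
                sl.simulate_pixel_intensity(bad, 100, 100.0)

    def test_mean_intensity_scaling(self):
        s = sl.simulate_pixel_intensity(0.05, 20000, 100.0, mean_intensity=40.0, seed=5)
        assert s.mean() == pytest.approx(40.0, rel=0.1)
        assert (s >= 0).all()

    def test_siegert_contrast_at_lag_zero(self):
        # g2(0) - 1 should equal beta; tau_c small so 1e4 frames give many
        # independent speckle samples (Monte-Carlo tolerance +-0.05).
        for beta in (1.0, 0.8):
            s = sl.simulate_pixel_intensity(0.02, 10000, 100.0, beta=beta, seed=42)
            g2_0 = np.mean(s**2) / np.mean(s) ** 2
            assert g2_0 - 1 == pytest.approx(beta, abs=0.05)

    def test_seeded_series_reproducible(self):
        a = sl.simulate_pixel_intensity(0.5, 200, 100.0, seed=9)
        b = sl.simulate_pixel_intensity(0.5, 200, 100.0, seed=9)
        np.testing.assert_array_equal(a, b)


class TestStack:
    def test_seeded_stack_bit_identical(self):
        spec = _spec(height=2, width=1, n_frames=10, seed=21)
        s1, _ = sl.simulate_stack(spec)
        s2, _ = sl.simulate_stack(spec)
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_pixel_stream_matches_scalar_simulator(self):
        # pixel (r, c) of a stack uses the stream (seed, flat_index), so the
        # stack path and the scalar path agree exactly
        spec = _spec(height=3, width=4, n_frames=50, background_tau_c=0.3, seed=77)
        stack, _ = sl.simulate_stack(spec)
        flat_idx = 1 * 4 + 2
        expected = sl.simulate_pixel_intensity(
            0.3, 50, 100.0, mean_intensity=100.0, seed=[77, flat_idx]
        )
        np.testing.assert_array_equal(stack.pixel_series(1, 2), expected)

    def test_memory_budget_enforced(self):
        spec = _spec(height=100, width=100, n_frames=10000)
        with pytest.raises(MemoryError):
            sl.simulate_stack(spec, memory_budget_bytes=10**6)

    def test_quantized_noisy_stack_contract(self):
        spec = _spec(height=4, width=4, n_frames=200, seed=5)
        noise = sl.NoiseSpec(shot_noise=True, bit_depth=12)
        stack, _ = sl.simulate_stack(spec, noise)
        assert (stack.frames >= 0).all()
        assert (stack.frames < 2**12).all()
        np.testing.assert_array_equal(stack.frames, np.rint(stack.frames))

    def test_lesion_ordering_through_dcs(self):
        spec = sl.standard_lesion_phantom(height=16, width=16, n_frames=3000, seed=2)
        stack, gt = sl.simulate_stack(spec)
        tmap = sl.dcs_map(stack)
        lesion = np.nanmean(tmap.tau_c[gt.lesion_mask])
        backgr = np.nanmean(tmap.tau_c[~gt.lesion_mask])
        assert lesion > backgr


class TestCameraNoise:
    def test_noiseless_identity(self):
        spec = _spec(height=2, width=2, n_frames=20)
        stack, _ = sl.simulate_stack(spec)
        out = sl.add_camera_noise(stack, sl.NoiseSpec(), seed=1)
        np.testing.assert_array_equal(out.frames, stack.frames)

    def test_read_noise_moment(self):
        stack = sl.SpeckleStack(np.full((10000, 1, 1), 100.0), fps=100.0)
        out = sl.add_camera_noise(stack, sl.NoiseSpec(read_noise_sigma=5.0), seed=2)
        assert out.frames.std() == pytest.approx(5.0, rel=0.1)

    def test_shot_noise_poisson_variance(self):
        stack = sl.SpeckleStack(np.full((20000, 1, 1), 100.0), fps=100.0)
        out = sl.add_camera_noise(stack, sl.NoiseSpec(shot_noise=True), seed=3)
        assert out.frames.var() == pytest.approx(100.0, rel=0.1)
        assert out.frames.mean() == pytest.approx(100.0, rel=0.05)


class TestStatisticalCalibration:
    def test_siegert_curve_convergence(self):
        """Pixel-averaged sample g2 stays within 0.05 of 1 + exp(-tau/tau_c)
        over lags up to 2 s for a 60 s record (the residual is dominated by
        the finite-record normalization bias, about 2*tau_f/T)."""
        tau_c, fps, n, npix = 0.5, 100.0, 6000, 200
        series = np.stack(
            [
                sl.simulate_pixel_intensity(tau_c, n, fps, seed=[303, i])
                for i in range(npix)
            ]
        )
        curves = np.stack(
            [sl.compute_g2(s, fps, max_lag=2.0).values for s in series]
        ).mean(axis=0)
        lags = np.arange(curves.size) / fps
        ideal = 1 + np.exp(-lags / tau_c)
        assert np.max(np.abs(curves - ideal)) < 0.05

    def test_analytic_curve_calibration_exact(self):
        # the simulator's target curve read back through the 1/e criterion
        # returns the requested tau_c to within one lag step
        fps = 100.0
        lags = np.arange(0, 201) / fps
        for tau_c in (0.1, 0.25, 0.5, 1.0):
            curve = sl.G2Curve(lags=lags, values=1 + np.exp(-lags / tau_c))
            est = sl.extract_tau_c(curve)
            assert est.valid
            assert abs(est.tau_c - tau_c) <= 1.0 / fps + 1e-12

    def test_round_trip_error_at_study_conditions(self):
        """Honest oracle level for the 60 s, 100 fps round trip: the median
        per-pixel relative error grows from ~10% at tau_c = 0.1 s to ~25% at
        1.0 s (intrinsic speckle statistics, ~sqrt(4 tau_c / T))."""
        fps, n = 100.0, 6000
        medians = {}
        for tau_c in (0.1, 0.5):
            errs = []
            for i in range(100):
                s = sl.simulate_pixel_intensity(tau_c, n, fps, seed=[404, i])
                est = sl.extract_tau_c(sl.compute_g2(s, fps, max_lag=2.0))
                if est.valid:
                    errs.append(abs(est.tau_c - tau_c) / tau_c)
            medians[tau_c] = np.median(errs)
        assert medians[0.1] < 0.15
        assert medians[0.5] < 0.30
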