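"""Phasor transform, universal-semicircle math and two-component unmixing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mobflim as mf
from mobflim.phasor import DecayStack, _pooled_phasor
from mobflim.synthetic import decay_pmf, wrapped_exponential_pmf

from conftest import make_stack, single_exp_stack


class TestSemicirclePoint:
    def test_zero_lifetime_is_one_zero(self, omega):
        assert mf.semicircle_point(0.0, omega) == (1.0, 0.0)

    def test_long_lifetime_limit_approaches_origin(self, omega):
        g, s = mf.semicircle_point(1e9, omega)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_at_3p5_ns(self, omega):
        g, s = mf.semicircle_point(3.5, omega)
        assert g == pytest.approx(0.2442, abs=5e-4)
        assert s == pytest.approx(0.4296, abs=5e-4)

    def test_negative_tau_rejected(self, omega):
        with pytest.raises(ValueError):
            mf.semicircle_point(-1.0, omega)

    @given(tau=st.floats(0.01, 50.0))
    @settings(deadline=None, max_examples=50)
    def test_always_on_the_universal_circle(self, tau):
        omega = 2 * math.pi / 12.5
        g, s = mf.semicircle_point(tau, omega)
        assert (g - 0.5) ** 2 + s ** 2 == pytest.approx(0.25, abs=1e-9)


class TestPhasorTransform:
    def test_all_photons_in_first_bin_gives_unit_phasor(self, acq):
        counts = np.zeros((acq.n_time_bins, 1, 1), dtype=int)
        counts[0, 0, 0] = 10_000
        stack = DecayStack(counts=counts, bin_centers=acq.bin_centers,
                           laser_period=acq.laser_period)
        p = mf.phasor_transform(stack)
        # all mass at t ~ half a bin width, not exactly 0
        g0, s0 = mf.semicircle_point(0.0, acq.omega)
        assert p.g[0, 0] == pytest.approx(g0, abs=2e-4)
        assert p.s[0, 0] == pytest.approx(s0, abs=2e-2)

    def test_wrapped_exponential_at_inverse_omega(self, acq):
        # omega*tau = 1 -> closed form (0.5, 0.5)
        stack = single_exp_stack(1.0 / acq.omega, acq)
        p = mf.phasor_transform(stack)
        assert p.g[0, 0] == pytest.approx(0.5, abs=1e-3)
        assert p.s[0, 0] == pytest.approx(0.5, abs=1e-3)

    def test_free_nadph_lifetime_closed_form(self, acq):
        stack = single_exp_stack(0.45, acq)
        p = mf.phasor_transform(stack)
        assert p.g[0, 0] == pytest.approx(0.9513, abs=1e-3)
        assert p.s[0, 0] == pytest.approx(0.2152, abs=1e-3)

    def test_zero_count_pixels_are_nan(self, acq):
        counts = np.zeros((acq.n_time_bins, 2, 1), dtype=int)
        counts[3, 0, 0] = 5
        stack = DecayStack(counts=counts, bin_centers=acq.bin_centers,
                           laser_period=acq.laser_period)
        p = mf.phasor_transform(stack)
        assert np.isfinite(p.g[0, 0])
        assert np.isnan(p.g[1, 0]) and np.isnan(p.s[1, 0])

    def test_bin_grid_not_spanning_period_rejected(self, acq):
        counts = np.ones((100, 1, 1), dtype=int)
        centers = np.linspace(0.02, 6.0, 100)  # does not span 12.5 ns
        with pytest.raises(ValueError, match="period"):
            DecayStack(counts=counts, bin_centers=centers, laser_period=12.5)

    @given(tau=st.floats(0.2, 5.0))
    @settings(deadline=None, max_examples=50)
    def test_binned_wrapped_decay_matches_closed_form(self, tau):
        acq = mf.AcquisitionConfig()
        stack = single_exp_stack(tau, acq, n_photons=1e9)
        p = mf.phasor_transform(stack)
        g, s = mf.semicircle_point(tau, acq.omega)
        assert p.g[0, 0] == pytest.approx(g, abs=1e-3)
        assert p.s[0, 0] == pytest.approx(s, abs=1e-3)

    def test_semicircle_residual_of_binned_decay_small(self, acq):
        for tau in (0.3, 1.0, 3.5):
            stack = single_exp_stack(tau, acq, n_photons=1e9)
            p = mf.phasor_transform(stack)
            resid = abs((p.g[0, 0] - 0.5) ** 2 + p.s[0, 0] ** 2 - 0.25)
            assert resid <= 1e-3


class TestLinearity:
    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_phasor_of_sum_is_count_weighted_mean(self, seed):
        acq = mf.AcquisitionConfig()
        rng = np.random.default_rng(seed)
        d1 = rng.integers(0, 1000, acq.n_time_bins)
        d2 = rng.integers(0, 1000, acq.n_time_bins)
        g1, s1 = _pooled_phasor(d1, acq.bin_centers, acq.omega)
        g2, s2 = _pooled_phasor(d2, acq.bin_centers, acq.omega)
        gs, ss = _pooled_phasor(d1 + d2, acq.bin_centers, acq.omega)
        w1, w2 = d1.sum(), d2.sum()
        assert gs == pytest.approx((w1 * g1 + w2 * g2) / (w1 + w2), abs=1e-12)
        assert ss == pytest.approx((w1 * s1 + w2 * s2) / (w1 + w2), abs=1e-12)


class TestCellPhasor:
    def _stack(self, acq, counts_2d, tau=1.5):
        pmf = decay_pmf(1.0, tau / 2, tau, acq)
        counts = np.rint(pmf[:, None, None] * counts_2d[None]).astype(int)
        return DecayStack(counts=counts, bin_centers=acq.bin_centers,
                          laser_period=acq.laser_period)

    def test_single_pixel_set_returns_that_pixel(self, acq):
        rng = np.random.default_rng(0)
        counts = rng.poisson(decay_pmf(0.6, 0.45, 3.0, acq)[:, None, None] * 5e4,
                             (acq.n_time_bins, 3, 3))
        stack = DecayStack(counts=counts, bin_centers=acq.bin_centers,
                           laser_period=acq.laser_period)
        p = mf.phasor_transform(stack)
        mask = np.zeros((3, 3), bool)
        mask[1, 2] = True
        g, s = mf.cell_phasor(p, mask, count_threshold=0)
        assert g == pytest.approx(p.g[1, 2], abs=1e-12)
        assert s == pytest.approx(p.s[1, 2], abs=1e-12)

    def test_weighted_mean_equals_pooled_decay_phasor(self, acq):
        rng = np.random.default_rng(1)
        counts = rng.poisson(decay_pmf(0.7, 0.45, 3.5, acq)[:, None, None] * 3e3,
                             (acq.n_time_bins, 8, 8))
        stack = DecayStack(counts=counts, bin_centers=acq.bin_centers,
                           laser_period=acq.laser_period)
        p = mf.phasor_transform(stack)
        mask = np.ones((8, 8), bool)
        g, s = mf.cell_phasor(p, mask, count_threshold=0)
        g2, s2 = _pooled_phasor(stack.pooled(mask), acq.bin_centers, acq.omega)
        assert g == pytest.approx(g2, abs=1e-12)
        assert s == pytest.approx(s2, abs=1e-12)

    def test_empty_or_zero_count_set_rejected(self, acq):
        stack = single_exp_stack(1.0, acq)
        p = mf.phasor_transform(stack)
        with pytest.raises(ValueError):
            mf.cell_phasor(p, np.zeros((1, 1), bool))


class TestDecomposeFixedFree:
    def test_pure_free_gives_alpha_zero_and_missing_tau(self, omega):
        pf = mf.semicircle_point(0.45, omega)
        fit = mf.decompose_fixed_free(pf, 0.45, omega)
        assert fit.alpha_bound == 0.0
        assert math.isnan(fit.tau_bound)

    def test_pure_bound_recovers_its_lifetime(self, omega):
        pb = mf.semicircle_point(3.5, omega)
        fit = mf.decompose_fixed_free(pb, 0.45, omega)
        assert fit.alpha_bound == pytest.approx(1.0, abs=1e-9)
        assert fit.tau_bound == pytest.approx(3.5, abs=1e-9)

    def test_documented_mixture_example(self, omega):
        fit = mf.decompose_fixed_free((0.4563, 0.3653), 0.45, omega)
        assert fit.alpha_bound == pytest.approx(0.700, abs=5e-3)
        assert fit.tau_bound == pytest.approx(3.50, abs=5e-2)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("tau_b", [1.0, 2.0, 3.5, 4.5])
    def test_noiseless_round_trip_exact(self, alpha, tau_b, omega):
        gs = mf.mixture_phasor(alpha, 0.45, tau_b, omega)
        fit = mf.decompose_fixed_free(gs, 0.45, omega)
        assert fit.alpha_bound == pytest.approx(alpha, abs=1e-9)
        if alpha > 0:
            assert fit.tau_bound == pytest.approx(tau_b, abs=1e-7)
        else:
            assert math.isnan(fit.tau_bound)

    def test_out_of_circle_point_projected_and_flagged(self, omega):
        gb, sb = mf.semicircle_point(3.5, omega)
        fit = mf.decompose_fixed_free((gb - 0.02, sb + 0.06), 0.45, omega)
        assert fit.residual_flag
        assert fit.valid
        assert fit.tau_bound > 0.45

    def test_tau_estimate_invariant_to_intensity_rescaling(self, acq):
        pmf = decay_pmf(0.6, 0.45, 3.2, acq)
        base = make_stack(pmf, acq, n_photons=1e6)
        taus = []
        for scale in (1, 7):
            stack = DecayStack(counts=base.counts * scale,
                               bin_centers=acq.bin_centers,
                               laser_period=acq.laser_period)
            p = mf.phasor_transform(stack)
            fit = mf.decompose_fixed_free((p.g[0, 0], p.s[0, 0]), 0.45, acq.omega)
            taus.append(fit.tau_bound)
        assert taus[1] == pytest.approx(taus[0], abs=1e-9)

    def test_stochastic_round_trip_typical_errors(self, acq):
        # at 1e4 photons the estimator is unbiased with tau noise at the
        # photon-statistics limit; check the typical (median) errors
        from mobflim.synthetic import sample_decay
        rng = np.random.default_rng(2024)
        a_err, t_err = [], []
        for _ in range(25):
            counts = sample_decay(0.7, 0.45, 3.5, 1e4, acq, rng)
            stack = DecayStack(counts=counts[:, None, None],
                               bin_centers=acq.bin_centers,
                               laser_period=acq.laser_period)
            p = mf.phasor_transform(stack)
            fit = mf.decompose_fixed_free((p.g[0, 0], p.s[0, 0]), 0.45, acq.omega)
            a_err.append(abs(fit.alpha_bound - 0.7))
            t_err.append(abs(fit.tau_bound - 3.5))
        assert np.median(a_err) <= 0.03
        assert np.median(t_err) <= 0.1


class TestTrajectoryFit:
    def test_exact_chord_recovers_both_lifetimes(self, omega):
        pf = np.array(mf.semicircle_point(0.45, omega))
        pb = np.array(mf.semicircle_point(3.5, omega))
        t = np.linspace(0.05, 0.95, 30)
        pts = pf + t[:, None] * (pb - pf)
        lo, hi = mf.fit_trajectory(pts, omega=omega)
        assert lo == pytest.approx(0.45, abs=1e-6)
        assert hi == pytest.approx(3.5, abs=1e-6)

    def test_two_semicircle_points_recovered_exactly(self, omega):
        pts = np.array([mf.semicircle_point(0.45, omega),
                        mf.semicircle_point(3.5, omega)])
        lo, hi = mf.fit_trajectory(pts, omega=omega)
        assert lo == pytest.approx(0.45, abs=1e-9)
        assert hi == pytest.approx(3.5, abs=1e-9)

    def test_noisy_chord_cloud_recovery(self, omega):
        rng = np.random.default_rng(0)
        pf = np.array(mf.semicircle_point(0.45, omega))
        pb = np.array(mf.semicircle_point(3.5, omega))
        t = rng.uniform(0, 1, 500)
        pts = pf + t[:, None] * (pb - pf) + rng.normal(0, 0.005, (500, 2))
        lo, hi = mf.fit_trajectory(pts, omega=omega)
        assert lo == pytest.approx(0.45, abs=0.05)
        assert hi == pytest.approx(3.5, abs=0.05)

    def test_degenerate_cloud_rejected(self, omega):
        pts = np.tile([0.4, 0.3], (20, 1))
        with pytest.raises(ValueError, match="degenerate"):
            mf.fit_trajectory(pts, omega=omega)

    def test_line_missing_circle_rejected(self, omega):
        pts = np.column_stack([np.linspace(0, 1, 20), np.full(20, 0.9)])
        with pytest.raises(ValueError):
            mf.fit_trajectory(pts, omega=omega)


class TestCalibration:
    def test_ideal_reference_yields_identity(self, acq):
        ref = single_exp_stack(1.0, acq)
        cal = mf.calibrate_from_reference(ref, 1.0)
        assert cal.phase_shift == pytest.approx(0.0, abs=2e-3)
        assert cal.modulation_factor == pytest.approx(1.0, abs=2e-3)

    def test_irf_blurred_reference_lands_back_on_semicircle(self):
        acq = mf.AcquisitionConfig(irf_sigma=0.1, frame_shape=(6, 6), seed=5)
        cell = mf.CellTruth(cell_id=1, population="ref", center=(2.5, 2.5), radius=2,
                            alpha_bound_true=1.0, tau_bound_true=1.0,
                            tau_free_true=0.5, total_photons=5e5, orr_true=0.2)
        from mobflim.synthetic import render_field
        field = render_field([cell], acq)
        stack = DecayStack(counts=field.decay_counts, bin_centers=acq.bin_centers,
                           laser_period=acq.laser_period)
        cal = mf.calibrate_from_reference(stack, 1.0)
        g, s = _pooled_phasor(stack.pooled(), acq.bin_centers, acq.omega)
        gc, sc = cal.apply(g, s)
        assert (gc - 0.5) ** 2 + sc ** 2 == pytest.approx(0.25, abs=5e-3)

    def test_calibration_is_not_idempotent(self):
        cal = mf.PhasorCalibration(phase_shift=0.2, modulation_factor=1.1)
        g1, s1 = cal.apply(0.4, 0.3)
        g2, s2 = cal.apply(g1, s1)
        assert (g2, s2) != pytest.approx((g1, s1))

    def test_zero_count_reference_rejected(self, acq):
        counts = np.zeros((acq.n_time_bins, 1, 1), dtype=int)
        ref = DecayStack(counts=counts, bin_centers=acq.bin_centers,
                         laser_period=acq.laser_period)
        with pytest.raises(ValueError):
            mf.calibrate_from_reference(ref, 1.0)


class TestMedianFilter:
    def _phasor(self, g):
        shape = g.shape
        return mf.PhasorImage(g=g, s=g * 0.5, total_counts=np.full(shape, 100.0),
                              omega=0.5, harmonic=1)

    def test_radius_zero_is_identity(self):
        g = np.random.default_rng(0).random((5, 5))
        p = self._phasor(g)
        out = mf.phasor_median_filter(p, radius=0)
        np.testing.assert_array_equal(out.g, p.g)

    def test_constant_field_unchanged(self):
        p = self._phasor(np.full((7, 7), 0.4))
        out = mf.phasor_median_filter(p, radius=1)
        np.testing.assert_allclose(out.g, 0.4)

    def test_single_outlier_replaced_by_surround(self):
        g = np.full((7, 7), 0.4)
        g[3, 3] = 0.9
        out = mf.phasor_median_filter(self._phasor(g), radius=1)
        assert out.g[3, 3] == pytest.approx(0.4)
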