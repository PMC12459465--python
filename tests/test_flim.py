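"""Decay model, fitting and binding-fraction estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from spinelab import flim, synthetic
from spinelab.exceptions import (
    InsufficientPhotonsError,
    InvalidParameterError,
    UndefinedMeanError,
)

# Frozen oracle: numerical convolution of exp(-u/2.6)*1(u>0) with a
# unit-area Gaussian of width 0.2, evaluated at t=1.5 with t0=1.0
# (scipy.integrate.quad, abs err < 1e-12).
H_QUADRATURE_VALUE = 0.8211301103494324


class TestDecayComponent:
    def test_collapses_to_pure_exponential_for_narrow_irf(self):
        # tau_g -> 0+: H(t0 + tau) -> exp(-1)
        val = flim.decay_component(2.6, t0=0.0, tau=2.6, tau_g=1e-8)
        assert val == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_causality_limit_before_pulse(self):
        assert flim.decay_component(-2.0, t0=0.0, tau=2.6, tau_g=0.2) < 1e-12

    def test_matches_quadrature_oracle(self):
        val = flim.decay_component(1.5, t0=1.0, tau=2.6, tau_g=0.2)
        assert val == pytest.approx(H_QUADRATURE_VALUE, abs=1e-12)

    def test_matches_fresh_quadrature_on_other_parameters(self):
        t, t0, tau, tau_g = 0.5, 0.0, 0.3, 0.05

        def integrand(u):
            return (
                np.exp(-u / tau)
                * np.exp(-((t - t0 - u) ** 2) / (2 * tau_g**2))
                / (np.sqrt(2 * np.pi) * tau_g)
            )

        expected, _ = quad(integrand, 0, np.inf, limit=200)
        assert flim.decay_component(t, t0, tau, tau_g) == pytest.approx(expected, rel=1e-10)

    def test_integral_over_time_equals_lifetime(self):
        total, _ = quad(lambda t: flim.decay_component(t, 1.0, 2.6, 0.2), -5, 200, limit=500)
        assert total == pytest.approx(2.6, rel=1e-6)

    def test_no_overflow_for_extreme_arguments(self):
        # small tau with long tail and far-early times must stay finite
        t = np.array([-50.0, 0.0, 20.0, 200.0])
        vals = flim.decay_component(t, t0=0.0, tau=0.05, tau_g=0.05)
        assert np.all(np.isfinite(vals)) and np.all(vals >= 0)

    @pytest.mark.parametrize("tau,tau_g", [(0.0, 0.2), (-1.0, 0.2), (2.6, 0.0), (2.6, -0.1)])
    def test_rejects_nonpositive_scales(self, tau, tau_g):
        with pytest.raises(InvalidParameterError):
            flim.decay_component(1.0, 0.0, tau, tau_g)


class TestModelCurve:
    t_grid = np.linspace(0.0, 12.0, 200)

    def test_pure_donor_reduces_to_single_component(self):
        p = flim.DecayParams(f0=5.0, p_ad=0.0, tau_d=2.6, tau_ad=1.3, tau_g=0.2, t0=1.0)
        expected = 5.0 * flim.decay_component(self.t_grid, 1.0, 2.6, 0.2)
        np.testing.assert_allclose(flim.model_curve(p, self.t_grid), expected)

    def test_fully_bound_reduces_to_single_component(self):
        p = flim.DecayParams(f0=5.0, p_ad=1.0, tau_d=2.6, tau_ad=1.3, tau_g=0.2, t0=1.0)
        expected = 5.0 * flim.decay_component(self.t_grid, 1.0, 1.3, 0.2)
        np.testing.assert_allclose(flim.model_curve(p, self.t_grid), expected)

    def test_generic_params_recompose(self):
        p = flim.DecayParams(f0=3.0, p_ad=0.4, tau_d=2.6, tau_ad=1.1, tau_g=0.15, t0=0.8)
        h_d = flim.decay_component(self.t_grid, 0.8, 2.6, 0.15)
        h_ad = flim.decay_component(self.t_grid, 0.8, 1.1, 0.15)
        np.testing.assert_allclose(
            flim.model_curve(p, self.t_grid), 3.0 * (0.6 * h_d + 0.4 * h_ad)
        )

    def test_linear_in_amplitude(self):
        p1 = flim.DecayParams(f0=1.0, p_ad=0.3)
        p2 = flim.DecayParams(f0=7.0, p_ad=0.3)
        np.testing.assert_allclose(
            flim.model_curve(p2, self.t_grid), 7.0 * flim.model_curve(p1, self.t_grid)
        )


class TestDecayParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(f0=1.0, p_ad=-0.1),
            dict(f0=1.0, p_ad=1.1),
            dict(f0=1.0, p_ad=0.3, tau_ad=2.6),  # not < tau_d
            dict(f0=1.0, p_ad=0.3, tau_ad=-1.0),
            dict(f0=1.0, p_ad=0.3, tau_g=0.0),
            dict(f0=0.0, p_ad=0.3),
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(InvalidParameterError):
            flim.DecayParams(**kwargs)

    def test_free_fraction_complements_bound(self):
        assert flim.DecayParams(f0=1.0, p_ad=0.3).p_d == pytest.approx(0.7)


class TestMeanArrivalTime:
    def test_pure_exponential_mean_equals_lifetime(self):
        p = flim.DecayParams(f0=1.0, p_ad=0.0, tau_d=2.6, tau_g=1e-4, t0=0.0)
        h = synthetic.simulate_photon_histogram(p, 200_000, seed=5)
        assert flim.mean_arrival_time(h) == pytest.approx(2.6, abs=0.02)

    def test_translation_equivariance(self, mixture_histogram):
        _, hist = mixture_histogram
        shifted = flim.PhotonHistogram(
            hist.bin_edges + 1.0, hist.counts, hist.period + 1.0
        )
        assert flim.mean_arrival_time(shifted) == pytest.approx(
            flim.mean_arrival_time(hist) + 1.0, abs=1e-9
        )

    def test_invariant_to_count_rescaling(self, mixture_histogram):
        _, hist = mixture_histogram
        scaled = flim.PhotonHistogram(hist.bin_edges, hist.counts * 5, hist.period)
        assert flim.mean_arrival_time(scaled) == pytest.approx(
            flim.mean_arrival_time(hist), abs=1e-12
        )

    def test_mixture_mean_matches_closed_form(self, mixture_histogram):
        params, hist = mixture_histogram
        expected = params.t0 + flim.mixture_mean_lifetime(0.3, 2.6, 1.3)
        assert flim.mean_arrival_time(hist) == pytest.approx(expected, abs=0.01)

    def test_empty_histogram_rejected(self):
        h = flim.PhotonHistogram(np.linspace(0, 10, 11), np.zeros(10), 10.0)
        with pytest.raises(UndefinedMeanError):
            flim.mean_arrival_time(h)


class TestBindingFractionFromMean:
    @pytest.mark.parametrize(
        "mean_tau,expected",
        [(2.6, 0.0), (1.3, 1.0), (2.3706, 0.300)],
    )
    def test_known_values(self, mean_tau, expected):
        assert flim.binding_fraction_from_mean(mean_tau, 2.6, 1.3) == pytest.approx(
            expected, abs=5e-4
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        p_ad=st.floats(0.0, 1.0),
        tau_ad_frac=st.floats(0.05, 0.95),
        tau_d=st.floats(0.5, 5.0),
    )
    def test_exactly_inverts_mixture_mean(self, p_ad, tau_ad_frac, tau_d):
        import warnings

        tau_ad = tau_ad_frac * tau_d
        mean_tau = flim.mixture_mean_lifetime(p_ad, tau_d, tau_ad)
        with warnings.catch_warnings():
            # rounding at the p_ad = 0 or 1 boundary can trip the
            # out-of-range warning by ~1e-17; irrelevant here
            warnings.simplefilter("ignore", UserWarning)
            recovered = flim.binding_fraction_from_mean(mean_tau, tau_d, tau_ad)
        assert recovered == pytest.approx(p_ad, abs=1e-9)

    def test_out_of_range_value_returned_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            p = flim.binding_fraction_from_mean(2.8, 2.6, 1.3)
        assert p < 0.0

    def test_clip_option_clamps(self):
        assert flim.binding_fraction_from_mean(2.8, 2.6, 1.3, clip=True) == 0.0

    def test_degenerate_denominator(self):
        with pytest.raises(ZeroDivisionError):
            flim.binding_fraction_from_mean(3.9, 2.6, 1.3)

    def test_requires_tau_ordering(self):
        with pytest.raises(InvalidParameterError):
            flim.binding_fraction_from_mean(2.0, 2.6, 2.6)


class TestFitDecay:
    def test_recovers_simulated_parameters(self, mixture_histogram):
        _, hist = mixture_histogram
        fit = flim.fit_decay(hist, tau_d_fixed=2.6)
        assert fit.converged
        assert fit.params.p_ad == pytest.approx(0.3, abs=0.02)
        assert fit.params.tau_ad == pytest.approx(1.3, abs=0.1)
        assert fit.params.t0 == pytest.approx(1.0, abs=0.02)

    def test_pure_donor_fits_near_zero_binding(self, donor_histogram):
        _, hist = donor_histogram
        fit = flim.fit_decay(hist, tau_d_fixed=2.6)
        assert fit.params.p_ad < 0.02

    def test_donor_lifetime_never_altered(self, mixture_histogram):
        _, hist = mixture_histogram
        fit = flim.fit_decay(hist, tau_d_fixed=2.6)
        assert fit.params.tau_d == 2.6

    def test_photon_floor_enforced(self, mixture_histogram):
        _, hist = mixture_histogram
        small = flim.PhotonHistogram(hist.bin_edges, (hist.counts > 1e9).astype(int), hist.period)
        with pytest.raises(InsufficientPhotonsError):
            flim.fit_decay(small)

    def test_wls_fallback_agrees_with_poisson(self, mixture_histogram):
        _, hist = mixture_histogram
        fit = flim.fit_decay(hist, objective="wls")
        assert fit.params.p_ad == pytest.approx(0.3, abs=0.03)

    def test_agrees_with_closed_form_estimator(self, mixture_histogram):
        params, hist = mixture_histogram
        fit = flim.fit_decay(hist)
        mean_tau = flim.mean_arrival_time(hist) - params.t0
        closed = flim.binding_fraction_from_mean(mean_tau, 2.6, 1.3)
        assert fit.params.p_ad == pytest.approx(closed, abs=0.02)


class TestLifetimeMap:
    def test_uniform_frame_gives_uniform_map(self, rng):
        p = flim.DecayParams(f0=1.0, p_ad=0.0, t0=1.0)
        stack, roi, _ = synthetic.simulate_flim_series(
            np.zeros(1), shape=(6, 6), photons_per_pixel=500,
            background_photons=500, seed=11,
        )
        m = flim.lifetime_map(stack.frames[0], stack.bin_edges, t0=1.0)
        assert m.mask.all()
        assert np.nanstd(m.mean_tau) < 0.2
        assert np.nanmean(m.mean_tau) == pytest.approx(2.6, abs=0.05)

    def test_zero_photon_pixel_masked(self):
        frame = np.zeros((2, 2, 10), dtype=int)
        frame[0, 0, 3] = 50
        m = flim.lifetime_map(frame, np.linspace(0, 10, 11), t0=0.0, min_photons=10)
        assert m.mask[0, 0] and not m.mask[1, 1]
        assert np.isnan(m.mean_tau[1, 1])

    def test_bound_region_has_shorter_lifetime(self):
        stack, roi, _ = synthetic.simulate_flim_series(
            np.full(1, 0.4), shape=(8, 8), photons_per_pixel=800,
            background_photons=800, seed=12,
        )
        m = flim.lifetime_map(stack.frames[0], stack.bin_edges, t0=1.0)
        bound_mean = np.nanmean(m.mean_tau[roi])
        free_mean = np.nanmean(m.mean_tau[~roi])
        assert bound_mean < free_mean
        assert bound_mean == pytest.approx(flim.mixture_mean_lifetime(0.4, 2.6, 1.3), abs=0.05)
        assert free_mean == pytest.approx(2.6, abs=0.05)


@pytest.fixture(scope="module")
def step_series():
    profile = np.where(np.arange(12) < 6, 0.2, 0.35)
    stack, roi, _ = synthetic.simulate_flim_series(
        profile, shape=(10, 10), photons_per_pixel=600, seed=21
    )
    return profile, stack, roi


class TestRoiBindingTimecourse:

    def test_step_recovered(self, step_series):
        profile, stack, roi = step_series
        params = flim.DecayParams(f0=1.0, p_ad=0.2, t0=1.0)
        trace = flim.roi_binding_timecourse(stack, roi, params, baseline_window=(0, 6))
        step = np.nanmean(trace.delta_p_ad[6:])
        assert step == pytest.approx(0.15, abs=0.02)

    def test_constant_series_has_flat_delta(self):
        stack, roi, _ = synthetic.simulate_flim_series(
            np.full(8, 0.25), shape=(8, 8), photons_per_pixel=1500, seed=22
        )
        params = flim.DecayParams(f0=1.0, p_ad=0.25, t0=1.0)
        trace = flim.roi_binding_timecourse(stack, roi, params, baseline_window=(0, 4))
        # ~24k pooled photons/frame give sigma(P_AD) ~ 0.02 per frame
        assert np.nanmax(np.abs(trace.delta_p_ad)) < 0.05
        assert abs(np.nanmean(trace.delta_p_ad)) < 0.02

    def test_low_photon_frames_masked(self, step_series):
        _, stack, roi = step_series
        params = flim.DecayParams(f0=1.0, p_ad=0.2, t0=1.0)
        trace = flim.roi_binding_timecourse(
            stack, roi, params, baseline_window=(0, 6), min_photons=10**9
        )
        assert np.isnan(trace.p_ad).all()

    def test_empty_roi_rejected(self, step_series):
        _, stack, _ = step_series
        params = flim.DecayParams(f0=1.0, p_ad=0.2)
        with pytest.raises(InvalidParameterError):
            flim.roi_binding_timecourse(
                stack, np.zeros(stack.frames.shape[1:3], bool), params, (0, 6)
            )


class TestQcFilterCells:
    def test_boundary_cases(self):
        kept = flim.qc_filter_cells({"a": 0.44, "b": 0.46, "c": 0.45})
        assert set(kept) == {"a", "c"}

    def test_array_input(self):
        out = flim.qc_filter_cells(np.array([0.1, 0.5, 0.45]))
        np.testing.assert_allclose(out, [0.1, 0.45])

    def test_default_threshold_is_45_percent(self):
        import inspect

        sig = inspect.signature(flim.qc_filter_cells)
        assert sig.parameters["threshold"].default == 0.45

    def test_invalid_threshold(self):
        with pytest.raises(InvalidParameterError):
            flim.qc_filter_cells({"a": 0.2}, threshold=0.0)
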