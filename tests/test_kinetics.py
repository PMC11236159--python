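"""Feature extraction: smoothing, segmentation, slopes, censoring, recovery."""

import numpy as np
import pytest
from conftest import slopes_bruteforce
from hypothesis import given, strategies as st

from hemoflow.kinetics import (DEFAULT_CONFIG, KineticsConfig, KineticsError,
                               bleeding_time, central_difference_slopes,
                               classify_segments, extract_features,
                               extract_growth_rate, extract_lag_time,
                               find_inflections, loess_smooth, mfi_fold_change,
                               segment_slopes)
from hemoflow.synth import TraceParams, generate_trace
from hemoflow.traces import AssayTrace


def make_trace(lag=100.0, slope=4.0, occ=400.0, noise=0.0, dt=5.0, amp=5.0,
               occludes=True, seed=0, censor=1200.0):
    plateau = slope * ((occ if occludes else censor) - lag)
    params = TraceParams(occludes=occludes, lag_duration_s=lag,
                         growth_slope_um2_s=slope, plateau_area_um2=plateau,
                         platelet_amplitude=amp,
                         occlusion_time_s=occ if occludes else None,
                         noise_sd_um2=noise, sampling_interval_s=dt)
    return generate_trace(params, np.random.default_rng(seed),
                          censor_time_s=censor)


class TestLoess:
    def test_reproduces_straight_line(self):
        t = np.arange(0.0, 500.0, 5.0)
        y = 3.0 * t + 7.0
        out = loess_smooth(t, y)
        assert np.allclose(out, y, rtol=1e-9, atol=1e-9 * np.abs(y).max())

    def test_reproduces_quadratic_at_degree_two(self):
        t = np.arange(0.0, 500.0, 5.0)
        y = 0.01 * t**2 - 2.0 * t + 5.0
        out = loess_smooth(t, y, KineticsConfig(loess_degree=2))
        assert np.allclose(out, y, rtol=1e-9, atol=1e-9 * np.abs(y).max())

    def test_reduces_noise_around_line(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 1000.0, 5.0)
        truth = 2.0 * t
        sigma = 50.0
        resid = []
        for _ in range(20):
            y = truth + rng.normal(0.0, sigma, t.size)
            resid.append(np.std(loess_smooth(t, y) - truth))
        assert np.mean(resid) < sigma

    def test_matches_statsmodels_lowess_at_degree_one(self):
        """Cross-check the linear-smoother implementation against the
        reference LOWESS (degree-1, no robustness iterations)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 300.0, 5.0)
        y = 0.02 * t**1.5 + rng.normal(0.0, 3.0, t.size)
        ours = loess_smooth(t, y, KineticsConfig(loess_degree=1, loess_span=0.4))
        ref = sm.nonparametric.lowess(y, t, frac=0.4, it=0, return_sorted=False)
        # implementations differ in neighbourhood ties; agreement to ~1%
        scale = np.abs(ref).max()
        assert np.max(np.abs(ours - ref)) < 0.02 * scale

    def test_too_few_points_rejected(self):
        with pytest.raises(KineticsError):
            loess_smooth(np.arange(3.0), np.arange(3.0))


class TestFindInflections:
    def test_lag_growth_bend_located(self):
        """Piecewise-linear lag->growth: one interior breakpoint at the bend."""
        t = np.arange(0.0, 600.0, 5.0)
        y = np.clip(t - 200.0, 0.0, None) * 4.0
        sm = loess_smooth(t, y)
        bps = find_inflections(sm, t)
        interior = [i for i in bps if 0 < i < t.size - 1]
        assert len(interior) == 1
        assert abs(t[interior[0]] - 200.0) <= 5.0

    def test_straight_line_has_no_interior_breakpoints(self):
        t = np.arange(0.0, 600.0, 5.0)
        sm = loess_smooth(t, 2.0 * t + 1.0)
        assert find_inflections(sm, t) == [0, t.size - 1]

    def test_logistic_breakpoint_at_midpoint(self):
        t = np.arange(0.0, 600.0, 5.0)
        y = 5000.0 / (1.0 + np.exp(-0.02 * (t - 300.0)))
        sm = loess_smooth(t, y)
        bps = find_inflections(sm, t)
        interior = [i for i in bps if 0 < i < t.size - 1]
        assert len(interior) == 1
        assert abs(t[interior[0]] - 300.0) <= 5.0


class TestSegmentSlopes:
    def test_exact_line_slope(self):
        t = np.arange(0.0, 300.0, 5.0)
        y = 4.0 * t + 10.0
        slopes, bounds = segment_slopes(y, t, [0, t.size - 1])
        assert slopes[0] == pytest.approx(4.0, abs=1e-12)

    def test_flat_segment_slope_zero(self):
        t = np.arange(0.0, 300.0, 5.0)
        slopes, _ = segment_slopes(np.full(t.size, 7.0), t, [0, t.size - 1])
        assert slopes[0] == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_mean_slope(self):
        """Mean central-difference slope of a*t^2 on [0,T] is ~a*T."""
        a, T, dt = 0.02, 500.0, 5.0
        t = np.arange(0.0, T + dt, dt)
        slopes, _ = segment_slopes(a * t**2, t, [0, t.size - 1])
        # interior mean misses the two endpoint slopes; discretization O(dt/T)
        assert slopes[0] == pytest.approx(a * T, rel=0.02)

    @given(st.integers(0, 1000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        t = np.cumsum(rng.uniform(1.0, 5.0, n))
        t -= t[0]
        y = rng.normal(0.0, 10.0, n)
        ours = central_difference_slopes(y, t)
        ref = slopes_bruteforce(y, t)
        assert np.allclose(ours[1:-1], ref[1:-1], rtol=1e-12, atol=1e-12)

    def test_unanalyzable_segments_rejected(self):
        t = np.arange(0.0, 20.0, 5.0)
        with pytest.raises(KineticsError):
            segment_slopes(np.zeros(4), t, [0, 3])


class TestClassification:
    def test_default_orientation(self):
        assert classify_segments(np.array([0.5, 3.0])) == ["lag", "growth"]

    def test_threshold_boundary_goes_to_lag(self):
        assert classify_segments(np.array([1.5])) == ["lag"]
        assert classify_segments(np.array([-1.5])) == ["lag"]

    def test_all_zero_slopes_are_lag(self):
        assert classify_segments(np.zeros(3)) == ["lag"] * 3

    def test_literal_inverted_rule_available(self):
        cfg = KineticsConfig(lag_rule="above_threshold")
        assert classify_segments(np.array([0.5, 3.0]), cfg) == ["growth", "lag"]


class TestLagAndGrowthExtraction:
    def test_growth_from_start_gives_zero_lag(self):
        t = np.arange(0.0, 100.0, 5.0)
        lag, flag = extract_lag_time(["growth"], [(0, t.size - 1)], t)
        assert lag == 0.0 and not flag

    def test_no_growth_flags_full_duration(self):
        t = np.arange(0.0, 100.0, 5.0)
        lag, flag = extract_lag_time(["lag"], [(0, t.size - 1)], t)
        assert lag == t[-1] and flag

    def test_duration_weighted_growth_rate(self):
        t = np.arange(0.0, 250.0, 5.0)
        bounds = [(0, 20), (20, 40)]          # 100 s each
        rate, flag = extract_growth_rate(["growth", "growth"],
                                         np.array([3.0, 5.0]), bounds, t)
        assert rate == pytest.approx(4.0) and not flag

    def test_no_growth_segments(self):
        rate, flag = extract_growth_rate(["lag"], np.array([0.2]),
                                         [(0, 10)], np.arange(11.0))
        assert rate == 0.0 and flag


class TestBleedingTime:
    def _t(self, dt=5.0):
        return np.arange(0.0, 1200.0 + dt, dt)

    def test_step_occlusion(self):
        t = self._t()
        flow = np.where(t >= 400.0, 0.0, 1.0)
        assert bleeding_time(flow, t) == (400.0, False)

    def test_never_occluding_censored_at_1200(self):
        t = self._t()
        assert bleeding_time(np.ones(t.size), t) == (1200.0, True)

    def test_short_dip_does_not_count(self):
        """A 120 s flow drop recovers; the permanent stop at 700 s counts."""
        t = self._t()
        flow = np.ones(t.size)
        flow[(t >= 500.0) & (t < 620.0)] = 0.0
        flow[t >= 700.0] = 0.0
        assert bleeding_time(flow, t) == (700.0, False)

    def test_exact_hold_duration_counts(self):
        t = self._t()
        flow = np.ones(t.size)
        flow[(t >= 900.0) & (t < 1080.0)] = 0.0
        assert bleeding_time(flow, t) == (900.0, False)

    def test_incomplete_trace_rejected_unless_early_stop(self):
        t = np.arange(0.0, 600.0, 5.0)
        with pytest.raises(KineticsError):
            bleeding_time(np.ones(t.size), t)
        bt, cens = bleeding_time(np.ones(t.size), t, early_stop=True)
        assert cens


class TestMfiFoldChange:
    def test_constant_series_is_unity(self):
        assert mfi_fold_change(np.full(10, 42.0)) == 1.0

    def test_peak_over_baseline(self):
        series = np.array([100.0, 600.0, 1500.0, 900.0])
        assert mfi_fold_change(series) == 15.0

    def test_monotone_series_peaks_at_end(self):
        series = np.linspace(50.0, 400.0, 20)
        assert mfi_fold_change(series) == series[-1] / series[0]

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(KineticsError):
            mfi_fold_change(np.array([0.0, 10.0]))


class TestExtractFeatures:
    def test_noiseless_round_trip(self):
        """Recover lag/growth/BT from a noiseless synthetic trace."""
        trace = make_trace(lag=100.0, slope=4.0, occ=400.0, noise=0.0)
        f = extract_features(trace)
        assert f.bleeding_time_s == 400.0 and f.censored is False
        assert abs(f.lag_time_s - 100.0) <= 5.0
        assert f.growth_rate_um2_s == pytest.approx(4.0, rel=0.02)
        assert f.max_mfi_fold_change == pytest.approx(5.0)
        assert f.lag_time_s <= f.bleeding_time_s

    @pytest.mark.parametrize("lag,slope,occ", [(50.0, 2.5, 300.0),
                                               (200.0, 8.0, 700.0),
                                               (150.0, 15.0, 1000.0)])
    def test_noiseless_recovery_across_parameters(self, lag, slope, occ):
        f = extract_features(make_trace(lag=lag, slope=slope, occ=occ))
        assert f.bleeding_time_s == occ
        assert abs(f.lag_time_s - lag) <= 5.0
        assert f.growth_rate_um2_s == pytest.approx(slope, rel=0.02)

    def test_flat_non_occluder(self):
        params = TraceParams(occludes=False, lag_duration_s=100.0,
                             growth_slope_um2_s=0.5, plateau_area_um2=50.0,
                             platelet_amplitude=1.2, noise_sd_um2=10.0)
        f = extract_features(generate_trace(params, np.random.default_rng(1)))
        assert f.bleeding_time_s == 1200.0 and f.censored is True
        assert f.growth_rate_um2_s == 0.0 and f.no_growth

    def test_deterministic(self):
        trace = make_trace(noise=20.0, seed=7)
        f1 = extract_features(trace)
        f2 = extract_features(trace)
        assert (f1.lag_time_s, f1.growth_rate_um2_s, f1.bleeding_time_s) == \
               (f2.lag_time_s, f2.growth_rate_um2_s, f2.bleeding_time_s)

    def test_noisy_growth_rate_median_error(self):
        """Noise at 5% of plateau: median growth error < 10% over replicates."""
        slope, errs = 6.0, []
        for seed in range(200):
            trace = make_trace(lag=150.0, slope=slope, occ=600.0,
                               noise=0.05 * slope * 450.0, seed=seed)
            f = extract_features(trace)
            errs.append(abs(f.growth_rate_um2_s - slope) / slope)
        assert np.median(errs) < 0.10

    def test_censoring_flag_consistency(self):
        """censored iff no qualifying sub-threshold flow run before 1200 s."""
        for occludes in (True, False):
            f = extract_features(make_trace(occ=800.0, occludes=occludes))
            assert f.censored is (not occludes)
            if not occludes:
                assert f.bleeding_time_s == DEFAULT_CONFIG.censor_time_s

    def test_trace_without_flow_signal(self):
        t = np.arange(0.0, 600.0, 10.0)
        trace = AssayTrace(time=t, area=np.clip(t - 100, 0, None) * 3.0,
                           shear_setting="venous")
        f = extract_features(trace)
        assert f.censored is None and "no_flow_signal" in f.flags
        assert f.growth_rate_um2_s == pytest.approx(3.0, rel=0.02)
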