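"""Synthetic cohort generator: trace shapes, determinism, calibration, coupling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hemoflow.synth import (ArmParams, CovariateCoupling, GeneratorConfig,
                            ImagingConfig, SynthError, TraceParams,
                            couple_covariates, generate_cohort,
                            generate_image_stack, generate_trace,
                            truncated_normal_exact_mean)
from hemoflow.traces import ARTERIAL, VENOUS


def occluder_params(lag=100.0, slope=4.0, occ=400.0, **kw):
    kw.setdefault("plateau_area_um2", slope * (occ - lag))
    return TraceParams(occludes=True, lag_duration_s=lag,
                       growth_slope_um2_s=slope, platelet_amplitude=5.0,
                       occlusion_time_s=occ, **kw)


class TestGenerateTrace:
    def test_piecewise_linear_construction(self):
        """Noiseless area is exactly slope * (t - lag) during growth."""
        trace = generate_trace(occluder_params(), np.random.default_rng(0))
        i = np.searchsorted(trace.time, 300.0)
        assert trace.area[i] == 800.0
        assert np.all(trace.area[trace.time < 100.0] == 0.0)
        assert np.all(trace.area[trace.time >= 400.0] == trace.area[-1])

    def test_flow_steps_at_occlusion(self):
        trace = generate_trace(occluder_params(occ=600.0), np.random.default_rng(0))
        assert np.all(trace.flow[trace.time < 600.0] == 1.0)
        assert np.all(trace.flow[trace.time >= 600.0] == 0.0)

    def test_non_occluder_flow_never_drops(self):
        params = TraceParams(occludes=False, lag_duration_s=100.0,
                             growth_slope_um2_s=3.0, plateau_area_um2=3300.0,
                             platelet_amplitude=2.0)
        trace = generate_trace(params, np.random.default_rng(0))
        assert np.all(trace.flow == 1.0)
        assert trace.time[-1] == 1200.0

    def test_same_seed_bit_identical(self):
        p = occluder_params(noise_sd_um2=25.0)
        t1 = generate_trace(p, np.random.default_rng(99))
        t2 = generate_trace(p, np.random.default_rng(99))
        assert np.array_equal(t1.area, t2.area)
        assert np.array_equal(t1.platelet_intensity, t2.platelet_intensity)
        assert np.array_equal(t1.flow, t2.flow)

    def test_peak_fold_change_equals_amplitude(self):
        trace = generate_trace(occluder_params(), np.random.default_rng(0))
        fc = trace.platelet_intensity.max() / trace.platelet_intensity[0]
        assert fc == pytest.approx(5.0)

    def test_occlusion_at_or_after_censor_rejected(self):
        with pytest.raises(SynthError):
            generate_trace(occluder_params(occ=1200.0,
                                           plateau_area_um2=4.0 * 1100.0),
                           np.random.default_rng(0))

    def test_nonpositive_sampling_interval_rejected(self):
        with pytest.raises(SynthError):
            generate_trace(occluder_params(sampling_interval_s=0.0),
                           np.random.default_rng(0))

    def test_occlusion_before_lag_rejected(self):
        with pytest.raises(SynthError):
            generate_trace(occluder_params(lag=500.0, occ=400.0,
                                           plateau_area_um2=100.0),
                           np.random.default_rng(0))

    def test_inconsistent_plateau_rejected(self):
        """Plateau must match slope x growth duration within 20% for occluders."""
        with pytest.raises(SynthError, match="inconsistent"):
            generate_trace(occluder_params(plateau_area_um2=2.0 * 4.0 * 300.0),
                           np.random.default_rng(0))

    @given(st.integers(0, 10_000))
    def test_noiseless_area_monotone_until_occlusion(self, seed):
        rng = np.random.default_rng(seed)
        lag = float(rng.integers(0, 60)) * 5.0
        occ = lag + float(rng.integers(12, 100)) * 5.0
        slope = float(rng.uniform(2.0, 20.0))
        trace = generate_trace(occluder_params(lag=lag, slope=slope, occ=min(occ, 1195.0),
                                               plateau_area_um2=slope * (min(occ, 1195.0) - lag)),
                               np.random.default_rng(seed))
        assert np.all(np.diff(trace.area) >= -1e-9)
        assert set(np.unique(trace.flow)) <= {0.0, 1.0}


class TestExactMeanTruncatedNormal:
    def test_mean_is_exact_despite_truncation(self):
        """A bound 2 SD from the target would bias a naive truncation."""
        dist = truncated_normal_exact_mean(10.02, 5.12, 0.3, 40.0)
        assert dist.mean() == pytest.approx(10.02, abs=1e-8)
        assert dist.support()[0] >= 0.3

    def test_naive_truncation_would_be_biased(self):
        from scipy import stats as sps

        naive = sps.truncnorm((0.3 - 10.02) / 5.12, (40.0 - 10.02) / 5.12,
                              loc=10.02, scale=5.12)
        assert abs(naive.mean() - 10.02) > 0.1

    def test_target_outside_bounds_rejected(self):
        with pytest.raises(SynthError):
            truncated_normal_exact_mean(5.0, 1.0, 6.0, 10.0)


class TestGenerateCohort:
    def test_group_sizes_and_shears(self):
        cfg = GeneratorConfig(n_trauma=8, n_control=3, seed=4)
        cohort = generate_cohort(cfg)
        assert (cohort.patients["group"] == "trauma").sum() == 8
        assert (cohort.patients["group"] == "control").sum() == 3
        assert len(cohort.traces) == 11 * 2
        assert all(k[1] in (VENOUS, ARTERIAL) for k in cohort.traces)
        assert all(k[0] in cohort.patients.index for k in cohort.traces)

    def test_empty_cohort_valid_provenance(self):
        cohort = generate_cohort(GeneratorConfig(n_trauma=0, n_control=0, seed=1))
        assert len(cohort.traces) == 0 and cohort.patients.empty
        assert cohort.provenance["seed"] == 1
        assert cohort.provenance["config_hash"]

    def test_controls_always_occlude(self):
        cohort = generate_cohort(GeneratorConfig(n_trauma=0, n_control=40, seed=2))
        assert bool(cohort.ground_truth["occludes"].all())
        assert not cohort.ground_truth["expected_censored"].any()

    def test_seed_determinism_byte_identical(self, tmp_path):
        frames = []
        for _ in range(2):
            cohort = generate_cohort(GeneratorConfig(n_trauma=6, n_control=2, seed=7))
            path = tmp_path / "cov.csv"
            cohort.patients.to_csv(path)
            frames.append(path.read_bytes())
            tr = cohort.traces[("T00001", VENOUS)]
            frames.append(tr.area.tobytes())
        assert frames[0] == frames[2] and frames[1] == frames[3]

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(n_trauma=4, n_control=0, seed=1))
        b = generate_cohort(GeneratorConfig(n_trauma=4, n_control=0, seed=2))
        assert not np.array_equal(a.traces[("T00001", VENOUS)].area,
                                  b.traces[("T00001", VENOUS)].area)

    def test_occluder_mean_matches_censored_mixture_algebra(self):
        """Occluder BTs average to (mean - (1-p)*censor)/p, so the cohort
        mean including censored assays recovers the configured target."""
        cfg = GeneratorConfig(n_trauma=3000, n_control=0, seed=5,
                              shear_settings=(VENOUS,), couplings=[])
        gt = generate_cohort(cfg).ground_truth
        assert gt["expected_bleeding_time_s"].mean() == pytest.approx(776.0, abs=15.0)
        closure = 100.0 * gt["occludes"].mean()
        assert closure == pytest.approx(65.0, abs=3.0)

    def test_unsatisfiable_coupling_rejected(self):
        with pytest.raises(SynthError):
            GeneratorConfig(couplings=[CovariateCoupling("vwf_pct", "venous_bt",
                                                         1.2, -1)]).validate()
        with pytest.raises(SynthError):
            GeneratorConfig(couplings=[CovariateCoupling("vwf_pct", "venous_bt",
                                                         0.5, 2)]).validate()

    def test_invalid_arm_probability_rejected(self):
        arms = GeneratorConfig().arms
        arms[("trauma", VENOUS)] = ArmParams(occlusion_probability=1.5,
                                             group_mean_bt_s=776.0)
        with pytest.raises(SynthError):
            GeneratorConfig(arms=arms).validate()


class TestCoupleCovariates:
    def _outputs(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"venous_bt": rng.normal(700.0, 300.0, n)},
                            index=[f"P{i}" for i in range(n)]), rng

    def test_r2_one_is_exactly_affine(self):
        outputs, rng = self._outputs(50)
        cov = couple_covariates(outputs,
                                [CovariateCoupling("c", "venous_bt", 1.0, +1)], rng)
        r = np.corrcoef(cov["c"], outputs["venous_bt"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_r2_target_recovered_at_scale(self):
        """Configured R^2 = 0.45 lands in [0.42, 0.48] at n = 10,000."""
        outputs, rng = self._outputs(10_000, seed=3)
        cov = couple_covariates(outputs,
                                [CovariateCoupling("c", "venous_bt", 0.45, +1)], rng)
        r = np.corrcoef(cov["c"], outputs["venous_bt"])[0, 1]
        assert 0.42 <= r * r <= 0.48

    def test_zero_target_is_independent(self):
        outputs, rng = self._outputs(10_000, seed=4)
        cov = couple_covariates(outputs,
                                [CovariateCoupling("c", "venous_bt", 0.0, +1)], rng)
        assert abs(np.corrcoef(cov["c"], outputs["venous_bt"])[0, 1]) < 0.05

    def test_sign_flips_correlation(self):
        outputs, rng = self._outputs(5000, seed=5)
        cov = couple_covariates(outputs,
                                [CovariateCoupling("c", "venous_bt", 0.5, -1)], rng)
        assert np.corrcoef(cov["c"], outputs["venous_bt"])[0, 1] < 0.0

    def test_achieved_r2_monotone_in_target(self):
        """For a fixed output vector, achieved R^2 increases with the target."""
        outputs, _ = self._outputs(5000, seed=6)
        achieved = []
        for r2 in (0.1, 0.3, 0.5, 0.7, 0.9):
            rng = np.random.default_rng(11)   # same noise draws throughout
            cov = couple_covariates(outputs,
                                    [CovariateCoupling("c", "venous_bt", r2, +1)],
                                    rng)
            achieved.append(np.corrcoef(cov["c"], outputs["venous_bt"])[0, 1] ** 2)
        assert all(a < b for a, b in zip(achieved, achieved[1:]))

    def test_too_few_patients_rejected(self):
        outputs, rng = self._outputs(2)
        with pytest.raises(SynthError):
            couple_covariates(outputs,
                              [CovariateCoupling("c", "venous_bt", 0.5, +1)], rng)

    def test_constant_output_rejected(self):
        outputs = pd.DataFrame({"venous_bt": [1200.0] * 10})
        with pytest.raises(SynthError, match="constant"):
            couple_covariates(outputs,
                              [CovariateCoupling("c", "venous_bt", 0.5, +1)],
                              np.random.default_rng(0))


class TestImageStackGeneration:
    def test_frame_count(self):
        """A 600 s trace imaged at 10 s intervals gives 61 frames."""
        trace = generate_trace(occluder_params(occ=500.0),
                               np.random.default_rng(0), censor_time_s=600.0)
        stack = generate_image_stack(trace, ImagingConfig(frame_interval_s=10.0),
                                     np.random.default_rng(0))
        assert stack.n_frames == 61

    def test_zero_area_trace_gives_background_frames(self):
        params = TraceParams(occludes=False, lag_duration_s=1100.0,
                             growth_slope_um2_s=0.5, plateau_area_um2=50.0,
                             platelet_amplitude=1.0)
        trace = generate_trace(params, np.random.default_rng(0))
        imaging = ImagingConfig(frame_interval_s=100.0)
        stack = generate_image_stack(trace, imaging, np.random.default_rng(0))
        assert np.all(stack.truth_masks[:-2] == False)  # noqa: E712
        assert np.allclose(stack.brightfield[0], imaging.brightfield_background)

    def test_mask_area_matches_trace_within_one_pixel(self):
        trace = generate_trace(occluder_params(), np.random.default_rng(0))
        imaging = ImagingConfig(frame_interval_s=20.0, um_per_pixel=1.0)
        stack = generate_image_stack(trace, imaging, np.random.default_rng(0))
        mask_areas = stack.truth_masks.sum(axis=(1, 2)) * 1.0
        assert np.max(np.abs(mask_areas - stack.truth_areas_um2)) <= 1.0

    def test_fluorescence_total_tracks_trace_intensity(self):
        trace = generate_trace(occluder_params(), np.random.default_rng(0))
        stack = generate_image_stack(trace, ImagingConfig(frame_interval_s=50.0),
                                     np.random.default_rng(0))
        totals = stack.fluorescence.sum(axis=(1, 2))
        expected = np.interp(stack.timestamps_s, trace.time,
                             trace.platelet_intensity)
        assert np.allclose(totals, expected, rtol=1e-9)

    def test_roi_too_small_rejected(self):
        trace = generate_trace(occluder_params(slope=20.0,
                                               plateau_area_um2=20.0 * 300.0),
                               np.random.default_rng(0))
        with pytest.raises(SynthError, match="cannot hold"):
            generate_image_stack(trace, ImagingConfig(roi_shape=(10, 10)),
                                 np.random.default_rng(0))
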