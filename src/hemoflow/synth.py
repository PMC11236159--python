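"""Seeded synthetic trauma-cohort generator.

Emulates the statistical structure of the ex vivo microfluidic hemostasis
study so every downstream stage (image quantification, kinetics, cohort
statistics) can be exercised and validated without patient data:

* two groups (trauma, healthy control) and two shear settings (venous
  ~150 1/s, arterial ~3500 1/s), one assay trace per patient per setting;
* traces with the observed lag -> growth -> occlusion-or-censoring shape,
  a normalized outlet-flow signal that steps to ~0 at occlusion, and a
  platelet fluorescence channel whose peak fold change is group dependent;
* group/shear-dependent occlusion probabilities and bleeding-time
  distributions calibrated so the cohort mean bleeding time *including*
  censored (1200 s) assays matches the study's printed group means
  (trauma 776 s venous / 890 s arterial; control 317 s / 327 s; closure
  65% / 43% / 100%);
* clinical covariates linearly coupled to realized assay outputs at
  configurable R^2 targets (defaults follow the reported significant
  correlations), everything else drawn from plausible clinical marginals;
* optional synthetic image stacks with per-frame ground-truth clot masks.

Calibration note: because non-occluding assays enter the printed group
means at the 1200 s censor value, the occluder bleeding-time distribution
is a truncated normal whose location is solved so that
``p * occluder_mean + (1 - p) * 1200`` equals the printed mean exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .traces import AssayTrace, VENOUS, ARTERIAL, SHEAR_SETTINGS
from .imagequant import ImageStack


class SynthError(ValueError):
    """Raised for invalid generator parameters."""


# ---------------------------------------------------------------------------
# Exact-mean truncated normal
# ---------------------------------------------------------------------------

def truncated_normal_exact_mean(target_mean: float, sd: float,
                                lower: float, upper: float):
    """Frozen truncated normal on [lower, upper] whose mean equals target_mean.

    The location parameter is solved numerically (the truncated mean is
    strictly increasing in the location). Naively truncating N(target, sd)
    would bias the mean whenever a bound sits within a few sd of the target.
    """
    if not (lower < target_mean < upper):
        raise SynthError(
            f"target mean {target_mean} outside truncation bounds ({lower}, {upper})")
    if sd <= 0:
        raise SynthError("sd must be positive")

    def gap(mu: float) -> float:
        a, b = (lower - mu) / sd, (upper - mu) / sd
        return sps.truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    mu = optimize.brentq(gap, lower - 12.0 * sd, upper + 12.0 * sd, xtol=1e-10)
    a, b = (lower - mu) / sd, (upper - mu) / sd
    return sps.truncnorm(a, b, loc=mu, scale=sd)


def _truncnorm(mean: float, sd: float, lower: float, upper: float):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return sps.truncnorm(a, b, loc=mean, scale=sd)


# ---------------------------------------------------------------------------
# Trace-level generation
# ---------------------------------------------------------------------------

@dataclass
class TraceParams:
    """Ground-truth parameters of one synthetic assay trace.

    ``plateau_area_um2`` is the area at which deposition stops; for
    occluders it must be consistent with ``growth_slope * (occlusion_time -
    lag_duration)`` within 20%.
    """

    occludes: bool
    lag_duration_s: float
    growth_slope_um2_s: float
    plateau_area_um2: float
    platelet_amplitude: float
    occlusion_time_s: Optional[float] = None
    noise_sd_um2: float = 0.0
    sampling_interval_s: float = 5.0

    def validate(self, censor_time_s: float = 1200.0) -> None:
        if self.sampling_interval_s <= 0:
            raise SynthError("sampling interval must be positive")
        if self.lag_duration_s < 0:
            raise SynthError("lag duration must be non-negative")
        if self.growth_slope_um2_s <= 0:
            raise SynthError("growth slope must be positive")
        if self.plateau_area_um2 <= 0:
            raise SynthError("plateau area must be positive")
        if self.platelet_amplitude < 0:
            raise SynthError("platelet amplitude must be non-negative")
        if self.noise_sd_um2 < 0:
            raise SynthError("noise sd must be non-negative")
        if self.occludes:
            if self.occlusion_time_s is None:
                raise SynthError("occluder needs an occlusion time")
            if self.occlusion_time_s >= censor_time_s:
                raise SynthError("occlusion time must precede the censor time")
            if self.occlusion_time_s <= self.lag_duration_s:
                raise SynthError("occlusion must follow the lag phase")
            implied = self.growth_slope_um2_s * (self.occlusion_time_s - self.lag_duration_s)
            if abs(self.plateau_area_um2 - implied) > 0.2 * implied:
                raise SynthError(
                    f"plateau area {self.plateau_area_um2:g} inconsistent with "
                    f"slope x growth duration = {implied:g} (>20%)")
        elif self.occlusion_time_s is not None:
            raise SynthError("non-occluder must not carry an occlusion time")


#: baseline platelet fluorescence (a.u.) at perfusion start
PLATELET_BASELINE = 100.0
#: relative noise on the fluorescence channel when trace noise is on
_INTENSITY_NOISE_FRAC = 0.01
#: absolute noise on the normalized flow signal when trace noise is on
_FLOW_NOISE_SD = 0.01


def generate_trace(params: TraceParams, rng: np.random.Generator,
                   shear_setting: str = VENOUS,
                   censor_time_s: float = 1200.0,
                   patient_id: Optional[str] = None,
                   slope_threshold_um2_s: float = 1.5) -> AssayTrace:
    """Piecewise-linear assay trace with the lag -> growth -> plateau shape.

    Area is ~0 (noise only) during the lag, rises at ``growth_slope`` until
    the plateau area, then holds. The flow signal is 1 before occlusion and
    0 after; non-occluders keep flow high to the censor time. The platelet
    channel tracks area so its peak fold change equals the configured
    amplitude. Ground truth (including the bleeding time and the growth
    rate an ideal analyst would report, given the lag/growth classification
    threshold) is stored on the trace for recovery tests.
    """
    params.validate(censor_time_s)
    dt = params.sampling_interval_s
    n_steps = int(round(censor_time_s / dt))
    if abs(n_steps * dt - censor_time_s) > 1e-9:
        raise SynthError("sampling interval must divide the trace duration")
    t = np.arange(n_steps + 1) * dt

    ramp = np.clip(t - params.lag_duration_s, 0.0, None) * params.growth_slope_um2_s
    area_clean = np.minimum(ramp, params.plateau_area_um2)
    if params.occludes:
        # deposition stops at occlusion even if the plateau was not reached
        area_clean = np.where(t >= params.occlusion_time_s,
                              area_clean[np.searchsorted(t, params.occlusion_time_s)],
                              area_clean)
        flow = np.where(t >= params.occlusion_time_s, 0.0, 1.0)
        expected_bt, censored = float(params.occlusion_time_s), False
    else:
        flow = np.ones_like(t)
        expected_bt, censored = float(censor_time_s), True

    peak = float(area_clean.max())
    if peak > 0:
        shape = area_clean / peak
    else:
        shape = np.zeros_like(area_clean)
    amp = params.platelet_amplitude
    intensity = PLATELET_BASELINE * (1.0 + (amp - 1.0) * shape)

    area = area_clean.copy()
    if params.noise_sd_um2 > 0:
        area = area + rng.normal(0.0, params.noise_sd_um2, t.size)
        intensity = intensity + rng.normal(
            0.0, _INTENSITY_NOISE_FRAC * PLATELET_BASELINE, t.size)
        flow = np.clip(flow + rng.normal(0.0, _FLOW_NOISE_SD, t.size), 0.0, 1.0)

    grows = params.growth_slope_um2_s > slope_threshold_um2_s and peak > 0
    truth = {
        "occludes": params.occludes,
        "lag_duration_s": params.lag_duration_s,
        "growth_slope_um2_s": params.growth_slope_um2_s,
        "occlusion_time_s": params.occlusion_time_s,
        "plateau_area_um2": params.plateau_area_um2,
        "platelet_amplitude": params.platelet_amplitude,
        "noise_sd_um2": params.noise_sd_um2,
        "expected_bleeding_time_s": expected_bt,
        "expected_censored": censored,
        "expected_growth_rate_um2_s": params.growth_slope_um2_s if grows else 0.0,
        "expected_lag_time_s": params.lag_duration_s if grows else float(t[-1]),
        "expected_max_mfi_fold_change": max(amp, 1.0) if peak > 0 else 1.0,
    }
    return AssayTrace(time=t, area=area, flow=flow,
                      platelet_intensity=intensity,
                      shear_setting=shear_setting, patient_id=patient_id,
                      ground_truth=truth)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmParams:
    """Distribution settings for one (group, shear setting) arm.

    ``group_mean_bt_s`` is the target cohort mean bleeding time *including*
    censored assays; the occluder distribution location is solved from it.
    Growth slopes are log-normal, truncated below at ``slope_min_um2_s`` so
    every depositing assay has an unambiguous growth phase. A fraction
    ``no_deposit_probability`` of non-occluders deposits essentially no
    clot (the little-to-no-deposition phenotype seen in a subset of trauma
    samples).
    """

    occlusion_probability: float
    group_mean_bt_s: float
    occluder_bt_sd_s: float = 150.0
    occluder_bt_min_s: float = 200.0
    lag_mean_s: float = 120.0
    lag_sd_s: float = 40.0
    log_slope_mean: float = np.log(4.0)
    log_slope_sd: float = 0.6
    slope_min_um2_s: float = 2.0
    slope_max_um2_s: float = 25.0
    amplitude_mean: float = 3.0
    amplitude_sd: float = 1.5
    amplitude_min: float = 1.0
    no_deposit_probability: float = 0.0
    noise_sd_um2: float = 15.0

    def validate(self) -> None:
        if not (0.0 <= self.occlusion_probability <= 1.0):
            raise SynthError("occlusion probability must lie in [0, 1]")
        if not (0.0 <= self.no_deposit_probability <= 1.0):
            raise SynthError("no-deposit probability must lie in [0, 1]")
        for name in ("occluder_bt_sd_s", "lag_sd_s", "log_slope_sd",
                     "amplitude_sd"):
            if getattr(self, name) <= 0:
                raise SynthError(f"{name} must be positive")


def default_arms() -> dict:
    """Study-condition defaults per (group, shear).

    Occlusion probabilities and group mean bleeding times follow the
    printed cohort results; dispersions, lag and slope scales, and platelet
    amplitudes are free parameters chosen at plausible assay scales (the
    printed +/- values are not usable as generator SDs for a censored
    mixture). Platelet amplitudes encode the attenuated platelet deposition
    of the trauma group.
    """
    return {
        ("trauma", VENOUS): ArmParams(
            occlusion_probability=0.65, group_mean_bt_s=776.0,
            lag_mean_s=140.0, lag_sd_s=50.0,
            log_slope_mean=np.log(4.0), log_slope_sd=0.5,
            amplitude_mean=3.0, amplitude_sd=1.5,
            no_deposit_probability=0.15),
        ("trauma", ARTERIAL): ArmParams(
            occlusion_probability=0.43, group_mean_bt_s=890.0,
            lag_mean_s=160.0, lag_sd_s=60.0,
            log_slope_mean=np.log(6.0), log_slope_sd=0.5,
            amplitude_mean=2.5, amplitude_sd=1.2,
            no_deposit_probability=0.15),
        ("control", VENOUS): ArmParams(
            occlusion_probability=1.0, group_mean_bt_s=317.0,
            occluder_bt_sd_s=60.0, lag_mean_s=100.0, lag_sd_s=30.0,
            log_slope_mean=np.log(4.0), log_slope_sd=0.3,
            amplitude_mean=12.0, amplitude_sd=3.0),
        ("control", ARTERIAL): ArmParams(
            occlusion_probability=1.0, group_mean_bt_s=327.0,
            occluder_bt_sd_s=60.0, lag_mean_s=110.0, lag_sd_s=30.0,
            log_slope_mean=np.log(6.0), log_slope_sd=0.3,
            amplitude_mean=15.0, amplitude_sd=4.0),
    }


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one clinical covariate."""

    name: str
    mean: float
    sd: float
    lower: float
    upper: float
    integer: bool = False
    dist: str = "normal"          # normal | lognormal | bernoulli
    groups: tuple = ("trauma", "control")
    exact_mean: bool = False      # solve truncated-normal location for the mean


@dataclass(frozen=True)
class CovariateCoupling:
    """Target linear coupling between a covariate and a realized assay output."""

    covariate: str
    output: str                   # e.g. "arterial_bt", "venous_growth_rate"
    r_squared: float
    sign: int                     # +1 or -1

    def validate(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise SynthError(f"R^2 target {self.r_squared} outside [0, 1]")
        if self.sign not in (-1, 1):
            raise SynthError("coupling sign must be +1 or -1")


def default_covariates() -> list:
    """Plausible clinical marginals; trauma WBC pinned at the printed mean."""
    T, C, B = ("trauma",), ("control",), ("trauma", "control")
    return [
        CovariateSpec("age_y", 40.0, 16.0, 18, 90, integer=True, groups=T),
        CovariateSpec("sex_male", 0.76, 0.0, 0, 1, dist="bernoulli", groups=T),
        CovariateSpec("injury_blunt", 0.65, 0.0, 0, 1, dist="bernoulli", groups=T),
        CovariateSpec("bmi", 26.5, 4.5, 16, 50, groups=T),
        CovariateSpec("iss", np.log(12.0), 0.65, 1, 75, integer=True,
                      dist="lognormal", groups=T),
        CovariateSpec("apache_ii", 13.0, 6.0, 0, 45, integer=True, groups=T),
        CovariateSpec("gcs", 9.0, 2.0, 3, 15, integer=True, groups=T),
        CovariateSpec("hr_bpm", 95.0, 20.0, 40, 180, groups=T),
        CovariateSpec("sbp_mmhg", 130.0, 25.0, 60, 220, groups=T),
        CovariateSpec("dbp_mmhg", 78.0, 15.0, 30, 130, groups=T),
        CovariateSpec("temp_c", 36.7, 0.6, 34, 40, groups=T),
        CovariateSpec("sao2_pct", 92.0, 3.0, 70, 100, groups=T),
        CovariateSpec("wbc_10e3_ul", 10.02, 5.12, 0.3, 40, groups=T, exact_mean=True),
        CovariateSpec("wbc_10e3_ul", 4.89, 1.06, 0.3, 40, groups=C, exact_mean=True),
        CovariateSpec("rbc_10e6_ul", 4.5, 0.6, 2, 7, groups=B),
        CovariateSpec("hgb_g_dl", 13.5, 1.8, 5, 20, groups=B),
        CovariateSpec("hct_pct", 40.0, 5.0, 15, 60, groups=B),
        CovariateSpec("mcv_fl", 90.0, 5.0, 70, 110, groups=B),
        CovariateSpec("mch_pg", 30.0, 2.5, 20, 40, groups=B),
        CovariateSpec("mchc_g_dl", 33.0, 1.2, 28, 38, groups=B),
        CovariateSpec("plt_10e3_ul", 250.0, 80.0, 20, 600, groups=B),
        CovariateSpec("mpv_fl", 9.5, 1.2, 6, 14, groups=B),
        CovariateSpec("pt_s", 13.5, 1.5, 9, 25, groups=B),
        CovariateSpec("ptt_s", 28.0, 4.0, 15, 60, groups=B),
        CovariateSpec("fgn_mg_dl", 280.0, 80.0, 50, 700, groups=B),
        CovariateSpec("vwf_pct", 180.0, 60.0, 10, 500, groups=T),
        CovariateSpec("vwf_pct", 110.0, 30.0, 10, 500, groups=C),
        CovariateSpec("d_dimer_ug_ml", 3.0, 2.0, 0.05, 20, groups=T),
        CovariateSpec("d_dimer_ug_ml", 0.5, 0.4, 0.05, 5, groups=C),
    ]


def default_couplings() -> list:
    """The reported significant covariate/assay-output correlations.

    Negative couplings of VWF, D-Dimer and MPV with venous bleeding time;
    positive SaO2 with arterial bleeding time; GCS (sign chosen positive),
    negative RBC and positive MCV with arterial growth rate.
    """
    return [
        CovariateCoupling("vwf_pct", "venous_bt", 0.35, -1),
        CovariateCoupling("d_dimer_ug_ml", "venous_bt", 0.33, -1),
        CovariateCoupling("mpv_fl", "venous_bt", 0.25, -1),
        CovariateCoupling("sao2_pct", "arterial_bt", 0.45, +1),
        CovariateCoupling("gcs", "arterial_growth_rate", 0.56, +1),
        CovariateCoupling("rbc_10e6_ul", "arterial_growth_rate", 0.38, -1),
        CovariateCoupling("mcv_fl", "arterial_growth_rate", 0.25, +1),
    ]


@dataclass
class GeneratorConfig:
    """Complete generator configuration; defaults are the study conditions."""

    n_trauma: int = 34
    n_control: int = 10
    censor_time_s: float = 1200.0
    occlusion_hold_s: float = 180.0
    sampling_interval_s: float = 5.0
    shear_settings: tuple = SHEAR_SETTINGS
    arms: dict = field(default_factory=default_arms)
    covariates: list = field(default_factory=default_covariates)
    couplings: list = field(default_factory=default_couplings)
    seed: int = 0

    def validate(self) -> None:
        if self.n_trauma < 0 or self.n_control < 0:
            raise SynthError("group sizes must be non-negative")
        if self.sampling_interval_s <= 0:
            raise SynthError("sampling interval must be positive")
        for shear in self.shear_settings:
            if shear not in SHEAR_SETTINGS:
                raise SynthError(f"unknown shear setting {shear!r}")
        for arm in self.arms.values():
            arm.validate()
        names = {(c.name, g) for c in self.covariates for g in c.groups}
        if len(names) < sum(len(c.groups) for c in self.covariates):
            raise SynthError("duplicate covariate spec for a group")
        coupled = set()
        for c in self.couplings:
            c.validate()
            if c.covariate in coupled:
                raise SynthError(f"covariate {c.covariate} coupled twice")
            coupled.add(c.covariate)

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, (ArmParams, CovariateSpec, CovariateCoupling)):
        return _as_jsonable(asdict(obj))
    if isinstance(obj, GeneratorConfig):
        return _as_jsonable({k: v for k, v in vars(obj).items()})
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Covariate coupling
# ---------------------------------------------------------------------------

def couple_covariates(outputs: pd.DataFrame, targets: Sequence[CovariateCoupling],
                      rng: np.random.Generator,
                      marginals: Optional[dict] = None) -> pd.DataFrame:
    """Covariates linearly coupled to realized assay outputs at target R^2.

    Each covariate is ``mean + sd * (sign * sqrt(R2) * z + sqrt(1-R2) * e)``
    with ``z`` the standardized output and ``e`` iid standard normal, so the
    population R^2 equals the target. Integer covariates are rounded and all
    are clamped to their physiologic bounds afterwards; at the default
    effect sizes both operations are rare/small enough to leave the R^2
    calibration intact.
    """
    if len(outputs) < 3:
        raise SynthError("need at least 3 patients to couple covariates")
    marginals = marginals or {}
    cols = {}
    for tgt in targets:
        tgt.validate()
        if tgt.output not in outputs.columns:
            raise SynthError(f"unknown assay output {tgt.output!r}")
        x = outputs[tgt.output].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise SynthError(f"non-finite values in output {tgt.output!r}")
        sd_x = x.std()
        if sd_x == 0:
            raise SynthError(f"output {tgt.output!r} is constant; coupling undefined")
        z = (x - x.mean()) / sd_x
        e = rng.standard_normal(x.size)
        spec = marginals.get(tgt.covariate)
        r2 = tgt.r_squared
        if spec is not None and spec.integer and spec.sd > 0:
            # integer covariates are reported rounded; rounding adds ~1/12
            # variance, so strengthen the continuous coupling so the
            # *delivered* covariate hits the target R^2
            r2 = min(r2 * (spec.sd**2 + 1.0 / 12.0) / spec.sd**2, 1.0)
        c = tgt.sign * np.sqrt(r2) * z + np.sqrt(1.0 - r2) * e
        if spec is not None:
            c = spec.mean + spec.sd * c
            c = np.clip(c, spec.lower, spec.upper)
            if spec.integer:
                c = np.round(c)
        cols[tgt.covariate] = c
    return pd.DataFrame(cols, index=outputs.index)


def _sample_marginal(spec: CovariateSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.dist == "bernoulli":
        return (rng.random(n) < spec.mean).astype(float)
    if spec.dist == "lognormal":
        v = np.exp(rng.normal(spec.mean, spec.sd, n))
    elif spec.exact_mean:
        v = truncated_normal_exact_mean(spec.mean, spec.sd, spec.lower,
                                        spec.upper).rvs(n, random_state=rng)
    else:
        v = _truncnorm(spec.mean, spec.sd, spec.lower, spec.upper).rvs(
            n, random_state=rng)
    v = np.clip(v, spec.lower, spec.upper)
    if spec.integer:
        v = np.round(v)
    return v


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """A simulated cohort: covariate table, traces, and ground truth."""

    patients: pd.DataFrame                      # index patient_id, incl. 'group'
    traces: dict                                # (patient_id, shear) -> AssayTrace
    ground_truth: pd.DataFrame                  # one row per (patient, shear)
    provenance: dict

    def traces_for(self, shear: str, group: Optional[str] = None) -> list:
        ids = (self.patients.index if group is None
               else self.patients.index[self.patients["group"] == group])
        return [self.traces[(pid, shear)] for pid in ids
                if (pid, shear) in self.traces]


def _snap(x, dt):
    return np.round(np.asarray(x, dtype=float) / dt) * dt


def _draw_arm(arm: ArmParams, n: int, rng: np.random.Generator,
              censor: float, hold: float, dt: float):
    """Vectorized per-assay parameter draws for one (group, shear) arm."""
    p = arm.occlusion_probability
    occludes = rng.random(n) < p
    bt_hi = censor - hold
    if p > 0:
        occ_mean = (arm.group_mean_bt_s - (1.0 - p) * censor) / p
        if not (arm.occluder_bt_min_s < occ_mean < bt_hi):
            raise SynthError(
                f"implied occluder mean {occ_mean:.1f} s outside "
                f"({arm.occluder_bt_min_s:g}, {bt_hi:g}) s")
        occ_dist = truncated_normal_exact_mean(
            occ_mean, arm.occluder_bt_sd_s, arm.occluder_bt_min_s, bt_hi)
        occ = _snap(occ_dist.rvs(n, random_state=rng), dt)
    else:
        occ = np.full(n, np.nan)
    # lag bounded away from occlusion (occluders) or the censor time
    ub = np.where(occludes, occ, censor) - 60.0
    a = (0.0 - arm.lag_mean_s) / arm.lag_sd_s
    b = (ub - arm.lag_mean_s) / arm.lag_sd_s
    lag = _snap(sps.truncnorm.ppf(rng.random(n), a, b,
                                  loc=arm.lag_mean_s, scale=arm.lag_sd_s), dt)
    lag = np.clip(lag, 0.0, None)
    a_s = (np.log(arm.slope_min_um2_s) - arm.log_slope_mean) / arm.log_slope_sd
    b_s = (np.log(arm.slope_max_um2_s) - arm.log_slope_mean) / arm.log_slope_sd
    slope = np.exp(sps.truncnorm.rvs(a_s, b_s, loc=arm.log_slope_mean,
                                     scale=arm.log_slope_sd, size=n,
                                     random_state=rng))
    amp = _truncnorm(arm.amplitude_mean, arm.amplitude_sd,
                     arm.amplitude_min, np.inf).rvs(n, random_state=rng)
    no_deposit = ~occludes & (rng.random(n) < arm.no_deposit_probability)
    return occludes, occ, lag, slope, amp, no_deposit


#: growth slope / plateau assigned to little-to-no-deposition assays
_NO_DEPOSIT_SLOPE = 0.5
_NO_DEPOSIT_PLATEAU = 50.0


def _realized_outputs(config: GeneratorConfig, ids: list, traces: dict,
                      truth: pd.DataFrame) -> pd.DataFrame:
    """Per-patient assay outputs the coupled covariates attach to.

    Couplings target the *measured* outputs — the quantities that enter the
    correlation analysis. Bleeding times are taken from ground truth (the
    detected value is identical, both being snapped to the sampling grid);
    growth rates and MFI fold changes are extracted from the generated
    traces with the default kinetics configuration, so the target R^2 holds
    against what the analysis stage actually reports.
    """
    from .kinetics import extract_features  # local import: keeps synth usable alone

    gt = truth[truth["patient_id"].isin(ids)]
    outputs = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    need = {c.output for c in config.couplings}
    for shear in config.shear_settings:
        sub = gt[gt["shear"] == shear].set_index("patient_id")
        outputs[f"{shear}_bt"] = sub["expected_bleeding_time_s"]
        measured_cols = {f"{shear}_growth_rate", f"{shear}_mfi_fold_change"}
        if measured_cols & need:
            feats = [extract_features(traces[(pid, shear)]) for pid in ids]
            outputs[f"{shear}_growth_rate"] = [f.growth_rate_um2_s for f in feats]
            outputs[f"{shear}_mfi_fold_change"] = [f.max_mfi_fold_change
                                                   for f in feats]
        else:
            outputs[f"{shear}_growth_rate"] = sub["expected_growth_rate_um2_s"]
            outputs[f"{shear}_mfi_fold_change"] = sub["expected_max_mfi_fold_change"]
    return outputs


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Generate a full synthetic cohort from the configuration.

    Deterministic in (seed, config): regeneration yields identical tables
    and traces. Trauma covariates named in the coupling targets are coupled
    to that patient's realized assay outputs; everything else is drawn from
    the configured marginals.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    censor, hold, dt = (config.censor_time_s, config.occlusion_hold_s,
                        config.sampling_interval_s)

    groups = [("trauma", "T", config.n_trauma), ("control", "C", config.n_control)]
    traces: dict = {}
    truth_rows = []
    patient_ids: dict = {g: [] for g, _, _ in groups}

    for group, prefix, n in groups:
        ids = [f"{prefix}{i + 1:05d}" for i in range(n)]
        patient_ids[group] = ids
        for shear in config.shear_settings:
            arm = config.arms[(group, shear)]
            occl, occ, lag, slope, amp, nodep = _draw_arm(arm, n, rng,
                                                          censor, hold, dt)
            for i, pid in enumerate(ids):
                if nodep[i]:
                    sl, plateau = _NO_DEPOSIT_SLOPE, _NO_DEPOSIT_PLATEAU
                else:
                    sl = slope[i]
                    end = occ[i] if occl[i] else censor
                    plateau = sl * (end - lag[i])
                params = TraceParams(
                    occludes=bool(occl[i]),
                    lag_duration_s=float(lag[i]),
                    growth_slope_um2_s=float(sl),
                    plateau_area_um2=float(plateau),
                    platelet_amplitude=float(amp[i]),
                    occlusion_time_s=float(occ[i]) if occl[i] else None,
                    noise_sd_um2=arm.noise_sd_um2,
                    sampling_interval_s=dt,
                )
                trace = generate_trace(params, rng, shear_setting=shear,
                                       censor_time_s=censor, patient_id=pid)
                traces[(pid, shear)] = trace
                truth_rows.append({"patient_id": pid, "group": group,
                                   "shear": shear, **trace.ground_truth})

    truth = pd.DataFrame(truth_rows)

    frames = []
    for group, _, n in groups:
        ids = patient_ids[group]
        if n == 0:
            continue
        df = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
        df["group"] = group
        coupled_names = ({c.covariate for c in config.couplings}
                         if group == "trauma" else set())
        marginals = {}
        for spec in config.covariates:
            if group not in spec.groups:
                continue
            marginals[spec.name] = spec
            if spec.name not in coupled_names:
                df[spec.name] = _sample_marginal(spec, n, rng)
        if group == "trauma" and config.couplings and n >= 3:
            outputs = _realized_outputs(config, ids, traces, truth)
            usable = [c for c in config.couplings if c.output in outputs.columns]
            coupled = couple_covariates(outputs, usable, rng, marginals)
            for col in coupled.columns:
                df[col] = coupled[col]
        frames.append(df)

    patients = (pd.concat(frames) if frames
                else pd.DataFrame(columns=["group"],
                                  index=pd.Index([], name="patient_id")))
    provenance = {"seed": config.seed, "config_hash": config.config_hash(),
                  "n_trauma": config.n_trauma, "n_control": config.n_control,
                  "shear_settings": list(config.shear_settings)}
    return CohortDataset(patients=patients, traces=traces,
                         ground_truth=truth, provenance=provenance)


# ---------------------------------------------------------------------------
# Synthetic image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Synthetic microscope settings for rendering a trace as an image stack."""

    frame_interval_s: float = 10.0
    um_per_pixel: float = 1.0
    roi_shape: tuple = (64, 160)          # (rows, cols) pixels
    brightfield_background: float = 1000.0
    clot_contrast: float = -400.0         # clots darker than background
    noise_sd: float = 0.0
    fluor_noise_sd: float = 0.0

    def validate(self) -> None:
        if self.frame_interval_s <= 0 or self.um_per_pixel <= 0:
            raise SynthError("frame interval and pixel size must be positive")
        if min(self.roi_shape) < 2:
            raise SynthError("ROI too small")


def _fill_order(shape: tuple) -> np.ndarray:
    """Deterministic pixel fill order: distance from the ROI centre."""
    rows, cols = shape
    r, c = np.mgrid[0:rows, 0:cols]
    d = (r - (rows - 1) / 2.0) ** 2 + (c - (cols - 1) / 2.0) ** 2
    return np.argsort(d.ravel(), kind="stable")


def generate_image_stack(trace: AssayTrace, imaging: ImagingConfig,
                         rng: np.random.Generator) -> ImageStack:
    """Render a trace as a two-channel image stack with ground-truth masks.

    The clot mask grows outward from the ROI centre with pixel count
    ``round(area / um_per_pixel^2)``, so mask area matches the trace within
    one pixel-quantization unit. Total fluorescence over the ROI equals the
    trace's platelet intensity (before optional noise): the baseline is
    spread uniformly and the excess placed on clot pixels.
    """
    imaging.validate()
    rows, cols = imaging.roi_shape
    upp = imaging.um_per_pixel
    capacity = rows * cols * upp * upp
    if float(np.max(trace.area)) > capacity:
        raise SynthError(
            f"ROI of {capacity:g} um^2 cannot hold peak area "
            f"{float(np.max(trace.area)):g} um^2")

    ft = np.arange(0.0, trace.duration + imaging.frame_interval_s / 2.0,
                   imaging.frame_interval_s)
    area = np.interp(ft, trace.time, trace.area)
    intensity = (np.interp(ft, trace.time, trace.platelet_intensity)
                 if trace.platelet_intensity is not None else None)

    order = _fill_order((rows, cols))
    npx_total = rows * cols
    bf = np.empty((ft.size, rows, cols))
    fl = np.empty_like(bf) if intensity is not None else None
    masks = np.zeros((ft.size, rows, cols), dtype=bool)
    for k in range(ft.size):
        npix = int(round(area[k] / (upp * upp)))
        m = np.zeros(npx_total, dtype=bool)
        m[order[:npix]] = True
        m = m.reshape(rows, cols)
        masks[k] = m
        frame = np.full((rows, cols), imaging.brightfield_background)
        frame[m] += imaging.clot_contrast
        if imaging.noise_sd > 0:
            frame = frame + rng.normal(0.0, imaging.noise_sd, frame.shape)
        bf[k] = frame
        if fl is not None:
            base = intensity[0] / npx_total
            f = np.full((rows, cols), base)
            excess = intensity[k] - intensity[0]
            if npix > 0:
                f[m] += excess / npix
            else:
                f += excess / npx_total
            if imaging.fluor_noise_sd > 0:
                f = f + rng.normal(0.0, imaging.fluor_noise_sd, f.shape)
            fl[k] = f
    return ImageStack(brightfield=bf, fluorescence=fl, timestamps_s=ft,
                      um_per_pixel=upp, shear_setting=trace.shear_setting,
                      patient_id=trace.patient_id,
                      truth_masks=masks, truth_areas_um2=area)
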