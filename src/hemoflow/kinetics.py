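"""Per-assay hemostatic feature extraction.

Turns an :class:`~hemoflow.traces.AssayTrace` into the four scalar readouts
of the assay:

* **bleeding time** — first time the normalized outlet flow stays below a
  small threshold for a sustained hold (default 3 min); assays that never
  seal are censored at the assay end (default 1200 s);
* **lag time** — duration of the slow initial deposition phase before rapid
  clot growth;
* **growth rate** — slope of the clot surface-area trace (um^2/s) during the
  growth phase;
* **maximum MFI fold change** — peak platelet fluorescence over its
  first-frame baseline.

Lag/growth segmentation follows the smoothing-then-inflection recipe: the
area trace (truncated at the bleeding time) is smoothed with a local
quadratic LOESS (tricube weights), segment boundaries are read off the sign
structure of the smoothed curvature, per-point slopes are computed on the
raw series by central differences with a three-point running average, and
segments are labelled lag when the absolute mean slope is at or below
1.5 um^2/s (growth above it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .traces import AssayTrace

LAG = "lag"
GROWTH = "growth"


class KineticsError(ValueError):
    """Raised when a trace cannot be analyzed under the configured rules."""


@dataclass(frozen=True)
class KineticsConfig:
    """Tunable parameters of the feature-extraction stage.

    Attributes
    ----------
    loess_span:
        Fraction of points in each local fit window (0 < span <= 1).
    loess_degree:
        Local polynomial degree, 1 or 2.
    slope_threshold:
        Lag/growth classification boundary in um^2/s.
    lag_rule:
        ``"below_threshold"`` (default): |slope| <= threshold is lag.
        ``"above_threshold"``: the literal inverted reading, |slope| >
        threshold is lag.
    occlusion_flow_eps:
        Normalized outlet flow below this counts as stopped.
    occlusion_hold_s:
        Flow must stay stopped at least this long to call occlusion.
    censor_time_s:
        Assay end; bleeding time is censored here.
    min_segment_points:
        Persistence length for curvature runs and minimum usable segment.
    curvature_rel_tol:
        Curvature below this fraction of the peak |curvature| is treated as
        flat when finding segment boundaries.
    """

    loess_span: float = 0.3
    loess_degree: int = 2
    slope_threshold: float = 1.5
    lag_rule: str = "below_threshold"
    occlusion_flow_eps: float = 0.05
    occlusion_hold_s: float = 180.0
    censor_time_s: float = 1200.0
    min_segment_points: int = 3
    curvature_rel_tol: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.loess_span <= 1.0):
            raise ValueError("loess_span must be in (0, 1]")
        if self.loess_degree not in (1, 2):
            raise ValueError("loess_degree must be 1 or 2")
        if self.slope_threshold <= 0:
            raise ValueError("slope_threshold must be positive")
        if self.lag_rule not in ("below_threshold", "above_threshold"):
            raise ValueError("lag_rule must be below_threshold or above_threshold")
        if self.occlusion_hold_s <= 0:
            raise ValueError("occlusion_hold_s must be positive")
        if self.censor_time_s <= self.occlusion_hold_s:
            raise ValueError("censor_time_s must exceed occlusion_hold_s")


DEFAULT_CONFIG = KineticsConfig()


@dataclass
class KineticFeatures:
    """Per-assay outputs of the kinetics stage."""

    bleeding_time_s: float
    censored: Optional[bool]
    lag_time_s: float
    growth_rate_um2_s: float
    max_area_um2: float
    max_mfi_fold_change: Optional[float] = None
    no_growth: bool = False
    shear_setting: Optional[str] = None
    patient_id: Optional[str] = None
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# LOESS smoothing (linear smoother; matrix cached per time grid)
# ---------------------------------------------------------------------------

_LOESS_CACHE: dict = {}
_LOESS_CACHE_MAX = 1024


def _loess_matrix(t: np.ndarray, span: float, degree: int) -> np.ndarray:
    """Smoothing matrix L with (L y)_i the local weighted polynomial fit at t_i.

    Tricube nearest-neighbour weights; window size k = max(ceil(span n),
    degree + 2, 5). LOESS without robustness iterations is linear in y, so
    the operator depends only on the time grid and can be reused across
    traces sharing it.
    """
    key = (t.tobytes(), span, degree)
    hit = _LOESS_CACHE.get(key)
    if hit is not None:
        return hit
    n = t.size
    k = min(n, max(int(np.ceil(span * n)), degree + 2, 5))
    # nearest-neighbour windows (contiguous for sorted t)
    d_all = np.abs(t[None, :] - t[:, None])
    idx = np.argpartition(d_all, k - 1, axis=1)[:, :k]            # (n, k)
    rows = np.arange(n)[:, None]
    d = d_all[rows, idx]
    dmax = d.max(axis=1, keepdims=True)
    dmax = np.where(dmax <= 0, 1.0, dmax)
    w = (1.0 - (d / dmax) ** 3) ** 3
    w = np.clip(w, 0.0, None)
    # guard against all-zero rows (k-th neighbour defines dmax, weight 0)
    w[np.arange(n), np.argmin(d, axis=1)] += 1e-12
    x = t[idx] - t[:, None]                                       # centred
    # normalize the local abscissa so the normal equations stay conditioned;
    # the fit is evaluated at x = 0, where only the intercept survives, so
    # the scaling cancels exactly
    s = np.maximum(np.abs(x).max(axis=1, keepdims=True), 1e-30)
    xs = x / s
    powers = np.arange(degree + 1)
    X = xs[:, :, None] ** powers[None, None, :]                   # (n, k, p+1)
    XW = X * w[:, :, None]
    G = np.einsum("nkp,nkq->npq", XW, X)                          # (n, p+1, p+1)
    G = G + 1e-12 * np.eye(degree + 1)[None, :, :] * np.maximum(
        np.trace(G, axis1=1, axis2=2)[:, None, None], 1.0)
    rhs = np.transpose(XW, (0, 2, 1))                             # (n, p+1, k)
    sol = np.linalg.solve(G, rhs)                                 # (n, p+1, k)
    L = np.zeros((n, n))
    np.put_along_axis(L, idx, sol[:, 0, :], axis=1)
    if len(_LOESS_CACHE) >= _LOESS_CACHE_MAX:
        _LOESS_CACHE.clear()
    _LOESS_CACHE[key] = L
    return L


def loess_smooth(time: np.ndarray, values: np.ndarray,
                 config: KineticsConfig = DEFAULT_CONFIG) -> np.ndarray:
    """LOESS-smooth a series, evaluated at the observed time points."""
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    n = time.size
    if n < max(5, int(np.ceil(config.loess_span * n))):
        raise KineticsError(f"too few points ({n}) for LOESS smoothing")
    return _loess_matrix(time, config.loess_span, config.loess_degree) @ values


# ---------------------------------------------------------------------------
# Inflection-point segmentation
# ---------------------------------------------------------------------------

def _second_difference(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Second divided difference on a possibly non-uniform grid (0 at ends)."""
    d2 = np.zeros_like(y)
    dt1 = t[1:-1] - t[:-2]
    dt2 = t[2:] - t[1:-1]
    d2[1:-1] = 2.0 * (y[2:] * dt1 - y[1:-1] * (dt1 + dt2) + y[:-2] * dt2) \
        / (dt1 * dt2 * (dt1 + dt2))
    return d2


def _sign_runs(s: np.ndarray):
    """(sign, start, stop) for maximal constant-sign runs (stop exclusive)."""
    runs = []
    start = 0
    for i in range(1, s.size + 1):
        if i == s.size or s[i] != s[start]:
            runs.append((int(s[start]), start, i))
            start = i
    return runs


def find_inflections(smoothed: np.ndarray, time: np.ndarray,
                     config: KineticsConfig = DEFAULT_CONFIG) -> list[int]:
    """Segment boundaries from the curvature of the smoothed series.

    Returns sorted indices, always including the first and last sample.
    Points are classified as convex/concave/flat against a tolerance of
    ``curvature_rel_tol`` times the peak |curvature| (the default 0.2 sits
    above the ~16% side-lobes a tricube local-quadratic fit rings around a
    slope discontinuity); only runs persisting
    for at least ``min_segment_points`` count. A convex run directly
    followed by a concave run (or vice versa) marks a true inflection and
    contributes the zero crossing between them; an isolated curvature run
    flanked by flat regions marks a slope change and contributes the
    location of its curvature peak.
    """
    y = np.asarray(smoothed, dtype=float)
    t = np.asarray(time, dtype=float)
    n = y.size
    bounds = {0, n - 1}
    if n < 2 * config.min_segment_points + 2:
        return sorted(bounds)
    d2 = _second_difference(y, t)
    scale = float(np.max(np.abs(d2)))
    dt_typ = float(np.median(np.diff(t)))
    if scale <= 1e-9 * max(1.0, float(np.max(np.abs(y)))) / dt_typ**2:
        return sorted(bounds)
    tol = config.curvature_rel_tol * scale
    s = np.zeros(n, dtype=int)
    s[d2 > tol] = 1
    s[d2 < -tol] = -1
    runs = [(sg, a, b) for sg, a, b in _sign_runs(s)
            if sg != 0 and (b - a) >= config.min_segment_points]
    interior: list[int] = []
    paired = [False] * len(runs)
    for j in range(len(runs) - 1):
        sg1, a1, b1 = runs[j]
        sg2, a2, b2 = runs[j + 1]
        gap = a2 - b1
        if sg1 == -sg2 and gap <= config.min_segment_points:
            # true inflection: zero crossing between opposite curvature runs
            lo, hi = b1 - 1, a2 + 1
            cross = lo + int(np.argmin(np.abs(d2[lo:hi])))
            interior.append(cross)
            paired[j] = paired[j + 1] = True
    for j, (sg, a, b) in enumerate(runs):
        if not paired[j]:
            # slope change flanked by flat curvature: peak marks the bend
            interior.append(a + int(np.argmax(np.abs(d2[a:b]))))
    return sorted(bounds | {i for i in interior if 0 < i < n - 1})


# ---------------------------------------------------------------------------
# Slopes and classification
# ---------------------------------------------------------------------------

def central_difference_slopes(values: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Per-point slope: central difference then 3-point running average.

    Endpoints (no central difference) are NaN; the running average at the
    edges of the valid range uses the available neighbours.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    n = y.size
    c = np.full(n, np.nan)
    c[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    r = np.full(n, np.nan)
    for i in range(1, n - 1):
        lo, hi = max(1, i - 1), min(n - 1, i + 2)
        r[i] = np.mean(c[lo:hi])
    return r


def segment_slopes(values: np.ndarray, time: np.ndarray,
                   breakpoints: Sequence[int],
                   config: KineticsConfig = DEFAULT_CONFIG):
    """Mean per-point slope of each segment between consecutive breakpoints.

    Slopes are computed on the **raw** series. Segment means use interior
    points only (breakpoint samples straddle two regimes and are excluded).
    Segments with fewer than ``min_segment_points`` interior slope samples
    are merged into the preceding segment (or following, for the first).

    Returns (slopes, segment index bounds) with bounds as (start, stop)
    sample-index pairs after merging.
    """
    bp = sorted(set(int(b) for b in breakpoints))
    if bp[0] != 0 or bp[-1] != len(values) - 1:
        raise KineticsError("breakpoints must include both trace ends")
    per_point = central_difference_slopes(values, time)
    segs = [(bp[i], bp[i + 1]) for i in range(len(bp) - 1)]

    def interior(a: int, b: int) -> np.ndarray:
        sl = per_point[max(a + 1, 1):min(b, len(values) - 1)]
        return sl[~np.isnan(sl)]

    # merge undersized segments
    merged: list[list[int]] = []
    for a, b in segs:
        if merged and interior(*merged[-1]).size < config.min_segment_points:
            merged[-1][1] = b
        elif merged and interior(a, b).size < config.min_segment_points:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    if merged and interior(*merged[0]).size < config.min_segment_points:
        if len(merged) > 1:
            merged[1][0] = merged[0][0]
            merged.pop(0)
    if not merged or any(interior(a, b).size < config.min_segment_points
                         for a, b in merged):
        raise KineticsError("trace unanalyzable: no segment with enough points")
    slopes = np.array([float(np.mean(interior(a, b))) for a, b in merged])
    return slopes, [(a, b) for a, b in merged]


def classify_segments(slopes: np.ndarray,
                      config: KineticsConfig = DEFAULT_CONFIG) -> list[str]:
    """Label each segment lag or growth against the slope threshold.

    Default orientation: |slope| <= threshold is lag (ties go to lag);
    ``lag_rule="above_threshold"`` flips the assignment.
    """
    labels = []
    for s in np.asarray(slopes, dtype=float):
        below = abs(s) <= config.slope_threshold
        if config.lag_rule == "below_threshold":
            labels.append(LAG if below else GROWTH)
        else:
            labels.append(GROWTH if below else LAG)
    return labels


def extract_lag_time(labels: Sequence[str], bounds: Sequence[tuple],
                     time: np.ndarray) -> tuple[float, bool]:
    """Time from perfusion start to the first growth segment.

    Returns (lag_time_s, no_growth). When no segment is labelled growth the
    lag spans the whole analyzed window and the flag is set.
    """
    for lab, (a, b) in zip(labels, bounds):
        if lab == GROWTH:
            return float(time[a]), False
    return float(time[-1]), True


def extract_growth_rate(labels: Sequence[str], slopes: np.ndarray,
                        bounds: Sequence[tuple], time: np.ndarray) -> tuple[float, bool]:
    """Duration-weighted mean slope of the first contiguous run of growth segments.

    Returns (growth_rate, no_growth); 0 with the flag set when nothing grew.
    """
    i = 0
    n = len(labels)
    while i < n and labels[i] != GROWTH:
        i += 1
    if i == n:
        return 0.0, True
    j = i
    while j < n and labels[j] == GROWTH:
        j += 1
    durations = np.array([time[b] - time[a] for a, b in bounds[i:j]])
    rate = float(np.average(slopes[i:j], weights=durations))
    return rate, False


def refine_lag_boundary(values: np.ndarray, time: np.ndarray,
                        bounds: Sequence[tuple], labels: Sequence[str],
                        config: KineticsConfig = DEFAULT_CONFIG):
    """Sharpen the lag-to-growth boundary on the raw series.

    LOESS smearing spreads the bend over roughly a window width, so the
    curvature-based boundary carries noise of that order. This step re-fits
    a continuous two-piece (hinge) linear model to the raw series in a
    window around the provisional boundary, placing the knot at the
    least-squares optimum — exact for a noiseless piecewise-linear bend.
    Returns possibly-updated segment bounds; no-op when nothing grew or
    growth starts at the first sample.
    """
    try:
        i = list(labels).index(GROWTH)
    except ValueError:
        return list(bounds)
    if i == 0:
        return list(bounds)
    n = len(time)
    k_win = max(int(np.ceil(config.loess_span * n)), 8)
    lo = max(bounds[i - 1][0], bounds[i][0] - k_win)
    hi = min(bounds[i][1], bounds[i][0] + k_win)
    if hi - lo < 4:
        return list(bounds)
    st, sy = time[lo:hi + 1], values[lo:hi + 1]
    best = None
    for k in range(1, st.size - 1):
        tb = st[k]
        X = np.column_stack([np.ones_like(st), np.clip(tb - st, 0.0, None),
                             np.clip(st - tb, 0.0, None)])
        beta, *_ = np.linalg.lstsq(X, sy, rcond=None)
        sse = float(np.sum((sy - X @ beta) ** 2))
        if best is None or sse < best[0]:
            best = (sse, lo + k)
    knot = best[1]
    out = [list(b) for b in bounds]
    out[i][0] = knot
    out[i - 1][1] = knot
    return [tuple(b) for b in out if b[1] > b[0]]


# ---------------------------------------------------------------------------
# Bleeding time and MFI fold change
# ---------------------------------------------------------------------------

def bleeding_time(flow: np.ndarray, time: np.ndarray,
                  config: KineticsConfig = DEFAULT_CONFIG,
                  early_stop: bool = False) -> tuple[float, bool]:
    """Occlusion detection with censoring.

    The bleeding time is the start of the earliest run in which the
    normalized outlet flow stays below ``occlusion_flow_eps`` for at least
    ``occlusion_hold_s``; a run reaching the end of the record counts its
    duration to the final sample. If no qualifying run exists by
    ``censor_time_s`` the assay is censored there. A trace that ends before
    the censor time without occluding is rejected as incomplete unless its
    ``early_stop`` flag is set.
    """
    flow = np.asarray(flow, dtype=float)
    time = np.asarray(time, dtype=float)
    below = flow < config.occlusion_flow_eps
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            run_end = time[j] if j < n else time[n - 1]
            if run_end - time[i] >= config.occlusion_hold_s:
                return float(time[i]), False
            i = j
        else:
            i += 1
    if time[-1] + 1e-9 < config.censor_time_s and not early_stop:
        raise KineticsError(
            f"trace ends at {time[-1]:g} s before censor time "
            f"{config.censor_time_s:g} s without occlusion")
    return float(config.censor_time_s), True


def mfi_fold_change(intensity: np.ndarray) -> float:
    """Maximum fluorescence fold change over the first-frame baseline."""
    intensity = np.asarray(intensity, dtype=float)
    baseline = intensity[0]
    if not np.isfinite(baseline) or baseline <= 0:
        raise KineticsError("platelet-intensity baseline must be positive")
    return float(np.max(intensity) / baseline)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def extract_features(trace: AssayTrace,
                     config: KineticsConfig = DEFAULT_CONFIG) -> KineticFeatures:
    """Full per-assay feature extraction.

    Lag/growth analysis runs on the window from perfusion start to the
    bleeding time (or the censor time), so the post-occlusion plateau does
    not dilute the growth rate.
    """
    flags: list[str] = []
    if trace.flow is not None:
        bt, censored = bleeding_time(trace.flow, trace.time, config,
                                     early_stop=trace.early_stop)
    else:
        bt, censored = float(trace.time[-1]), None
        flags.append("no_flow_signal")

    win = trace.time <= bt + 1e-9
    t_w = trace.time[win]
    a_w = trace.area[win]

    min_pts = max(5, 2 * config.min_segment_points + 2)
    if t_w.size < min_pts:
        lag, rate, no_growth = float(t_w[-1]), 0.0, True
        flags.append("window_too_short")
    else:
        smoothed = loess_smooth(t_w, a_w, config)
        bps = find_inflections(smoothed, t_w, config)
        try:
            slopes, bounds = segment_slopes(a_w, t_w, bps, config)
        except KineticsError:
            lag, rate, no_growth = float(t_w[-1]), 0.0, True
            flags.append("unsegmentable")
        else:
            labels = classify_segments(slopes, config)
            refined = refine_lag_boundary(a_w, t_w, bounds, labels, config)
            if refined != bounds:
                bps = sorted({b[0] for b in refined} | {refined[-1][1]})
                slopes, bounds = segment_slopes(a_w, t_w, bps, config)
                labels = classify_segments(slopes, config)
            lag, no_growth_lag = extract_lag_time(labels, bounds, t_w)
            rate, no_growth = extract_growth_rate(labels, slopes, bounds, t_w)
            no_growth = no_growth or no_growth_lag

    if no_growth:
        flags.append("no_growth")

    fc = None
    if trace.platelet_intensity is not None:
        fc = mfi_fold_change(trace.platelet_intensity)

    return KineticFeatures(
        bleeding_time_s=bt,
        censored=censored,
        lag_time_s=min(lag, bt),
        growth_rate_um2_s=max(rate, 0.0),
        max_area_um2=float(np.max(trace.area)),
        max_mfi_fold_change=fc,
        no_growth=no_growth,
        shear_setting=trace.shear_setting,
        patient_id=trace.patient_id,
        flags=flags,
    )


def features_to_frame(features: Sequence[KineticFeatures]):
    """Tabulate features, one row per assay."""
    import pandas as pd

    return pd.DataFrame([{
        "patient_id": f.patient_id,
        "shear": f.shear_setting,
        "bleeding_time_s": f.bleeding_time_s,
        "censored": f.censored,
        "lag_time_s": f.lag_time_s,
        "growth_rate_um2_s": f.growth_rate_um2_s,
        "max_area_um2": f.max_area_um2,
        "max_mfi_fold_change": f.max_mfi_fold_change,
        "no_growth": f.no_growth,
        "flags": ";".join(f.flags),
    } for f in features])
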