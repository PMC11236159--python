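"""Cohort-level statistics.

Group comparisons (unpaired t-tests, Welch form by default), closure
frequencies, injury-severity subgrouping, and the exploratory pairwise
Pearson correlation matrix linking microfluidic features to clinical
covariates. Matching the exploratory intent, no multiplicity adjustment is
applied by default (a Benjamini-Hochberg option is available), missing
values are handled by pairwise-complete deletion, and censored bleeding
times enter at their 1200 s face value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


@dataclass
class GroupComparison:
    """Two-sample location comparison summary."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    df: float
    p_value: float
    equal_var: bool = False
    available: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "label_a", "label_b", "n_a", "n_b", "mean_a", "mean_b",
            "sd_a", "sd_b", "t_statistic", "df", "p_value", "equal_var",
            "available", "note")}


def welch_ttest(a: Sequence[float], b: Sequence[float],
                labels: tuple = ("a", "b"), equal_var: bool = False) -> GroupComparison:
    """Unpaired two-sample t-test, Welch (unequal variance) by default.

    With unequal group sizes (the study compares 34 trauma patients with 10
    controls) Welch's form is the safer default; ``equal_var=True`` gives
    the classical Student variant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            t, df, p = 0.0, float(a.size + b.size - 2), 1.0
        else:
            raise StatsError("zero variance in both groups with unequal means")
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        label_a=labels[0], label_b=labels[1], n_a=int(a.size), n_b=int(b.size),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        t_statistic=t, df=df, p_value=p, equal_var=equal_var)


@dataclass
class ClosureFrequency:
    """Fraction of assays that achieved hemostatic closure before censoring."""

    percent: float
    n_closed: int
    n_total: int


def closure_frequency(features) -> ClosureFrequency:
    """Percent of assays with an uncensored bleeding time.

    Accepts a sequence of :class:`~hemoflow.kinetics.KineticFeatures` or a
    features DataFrame with a ``censored`` column.
    """
    if isinstance(features, pd.DataFrame):
        censored = features["censored"].astype(bool).to_numpy()
    else:
        censored = np.array([bool(f.censored) for f in features])
    n = censored.size
    if n == 0:
        raise StatsError("closure frequency of an empty cohort is undefined")
    closed = int(np.sum(~censored))
    return ClosureFrequency(percent=100.0 * closed / n, n_closed=closed, n_total=n)


@dataclass
class CorrelationResult:
    """Pearson correlation of one variable pair (pairwise complete)."""

    var_a: str
    var_b: str
    n: int
    r: float
    r_squared: float
    p_value: float
    available: bool = True
    note: str = ""


def pearson_pairwise(table: pd.DataFrame, min_n: int = 3,
                     fdr: bool = False) -> pd.DataFrame:
    """All-pairs Pearson correlations with pairwise-complete deletion.

    Returns a long-format table (var_a, var_b, n, r, r_squared, p_value,
    available, note) over unordered pairs of numeric columns. Pairs with
    fewer than ``min_n`` complete observations or a constant variable are
    marked unavailable instead of raising. ``fdr=True`` appends a
    Benjamini-Hochberg adjusted ``q_value`` column (off by default to match
    the exploratory, unadjusted reading of the matrix).
    """
    num = table.select_dtypes(include=[np.number])
    cols = list(num.columns)
    rows = []
    for i, va in enumerate(cols):
        for vb in cols[i + 1:]:
            x = num[va].to_numpy(dtype=float)
            y = num[vb].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < min_n:
                rows.append(CorrelationResult(va, vb, n, np.nan, np.nan, np.nan,
                                              available=False, note="too few pairs"))
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                rows.append(CorrelationResult(va, vb, n, np.nan, np.nan, np.nan,
                                              available=False, note="constant variable"))
                continue
            r, p = sps.pearsonr(xs, ys)
            rows.append(CorrelationResult(va, vb, n, float(r), float(r) ** 2,
                                          float(p)))
    out = pd.DataFrame([vars(r) for r in rows])
    if fdr and len(out):
        q = np.full(len(out), np.nan)
        ok = out["available"].to_numpy() & np.isfinite(out["p_value"].to_numpy())
        if ok.any():
            q[ok] = sps.false_discovery_control(out.loc[ok, "p_value"], method="bh")
        out["q_value"] = q
    return out


def correlation_matrix(pairs: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Pivot the long-format pair table into a symmetric matrix (unit diagonal)."""
    names = sorted(set(pairs["var_a"]) | set(pairs["var_b"]))
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for _, row in pairs.iterrows():
        v = row[value] if row["available"] else np.nan
        mat.loc[row["var_a"], row["var_b"]] = v
        mat.loc[row["var_b"], row["var_a"]] = v
    return mat


def subgroup_by_iss(covariates: pd.DataFrame, features: pd.DataFrame,
                    cutoff: float = 16.0) -> dict:
    """Bleeding-time comparison of polytrauma (ISS >= cutoff) vs minor trauma.

    Run per shear setting on trauma patients; a subgroup with fewer than two
    members yields an unavailable comparison rather than an error.
    """
    trauma = covariates[covariates["group"] == "trauma"]
    if "iss" not in trauma.columns or trauma["iss"].isna().any():
        raise StatsError("ISS must be present for all trauma patients")
    out = {}
    for shear, sub in features.groupby("shear"):
        sub = sub.set_index("patient_id").join(trauma["iss"], how="inner")
        poly = sub.loc[sub["iss"] >= cutoff, "bleeding_time_s"]
        minor = sub.loc[sub["iss"] < cutoff, "bleeding_time_s"]
        if len(poly) < 2 or len(minor) < 2:
            out[shear] = GroupComparison(
                label_a=f"ISS>={cutoff:g}", label_b=f"ISS<{cutoff:g}",
                n_a=len(poly), n_b=len(minor),
                mean_a=np.nan, mean_b=np.nan, sd_a=np.nan, sd_b=np.nan,
                t_statistic=np.nan, df=np.nan, p_value=np.nan,
                available=False, note="subgroup too small")
        else:
            out[shear] = welch_ttest(poly, minor,
                                     labels=(f"ISS>={cutoff:g}", f"ISS<{cutoff:g}"))
    return out


def format_median_iqr(values, fmt: str = "{:.0f}") -> str:
    """Printed style for demographics: ``median (q1-q3)``."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    med, q1, q3 = np.median(v), *np.percentile(v, [25, 75])
    return f"{fmt.format(med)} ({fmt.format(q1)}–{fmt.format(q3)})"


def summarize_cohort(covariates: pd.DataFrame, features: pd.DataFrame) -> dict:
    """Table-style numeric summaries of the cohort.

    Returns ``{"demographics": DataFrame, "features": DataFrame}``:
    per-group median (IQR) for numeric covariates (n (%) for binary ones)
    and per group x shear mean +/- SD, n for assay features. Covariates
    entirely missing in a group are omitted for that group.
    """
    if covariates.empty:
        raise StatsError("empty cohort")
    demo_rows = []
    for group, sub in covariates.groupby("group"):
        for col in sub.columns:
            if col == "group":
                continue
            v = pd.to_numeric(sub[col], errors="coerce").dropna()
            if v.empty:
                continue
            if set(np.unique(v)) <= {0.0, 1.0}:
                k = int(v.sum())
                text = f"{k}/{len(v)} ({100.0 * k / len(v):.0f}%)"
            else:
                text = format_median_iqr(v, "{:.1f}" if v.abs().max() < 100 else "{:.0f}")
            demo_rows.append({"group": group, "variable": col, "n": len(v),
                              "summary": text})
    feat_rows = []
    numeric = ["bleeding_time_s", "lag_time_s", "growth_rate_um2_s",
               "max_area_um2", "max_mfi_fold_change"]
    merged = features.merge(covariates[["group"]], left_on="patient_id",
                            right_index=True, how="left")
    for (group, shear), sub in merged.groupby(["group", "shear"]):
        for col in numeric:
            v = pd.to_numeric(sub[col], errors="coerce").dropna()
            if v.empty:
                continue
            feat_rows.append({"group": group, "shear": shear, "variable": col,
                              "n": len(v), "mean": float(v.mean()),
                              "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan})
    return {"demographics": pd.DataFrame(demo_rows),
            "features": pd.DataFrame(feat_rows)}


def plot_correlation_heatmap(pairs: pd.DataFrame, path) -> None:
    """Save a correlation-matrix heatmap (Pearson R, symmetric) as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = correlation_matrix(pairs)
    fig, ax = plt.subplots(figsize=(0.35 * len(mat) + 2,) * 2)
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(mat)), mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson R")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
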