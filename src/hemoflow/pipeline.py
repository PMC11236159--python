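"""Reproducible end-to-end runs: simulate -> quantify -> kinetics -> stats -> report.

A run writes a deterministic directory layout::

    <out>/
      run.log
      provenance.json
      cohort/covariates.csv, ground_truth.csv
      traces/traces.csv
      images/<patient>_<shear>.tif (+ .json sidecars)   [optional subset]
      traces/quantified_traces.csv                      [if images rendered]
      features/features.csv
      stats/correlations.csv, comparisons.json, summary_demographics.csv,
            summary_features.csv [, correlation_heatmap.png]
      report.json

Re-running with the same configuration and seed reproduces every CSV/JSON
byte for byte. Units are seconds, um^2 and 1/s throughout; CSVs are
RFC-4180 UTF-8 with '.' decimal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imagequant import read_stack_tiff, stack_to_trace, write_stack_tiff
from .kinetics import (DEFAULT_CONFIG, KineticsConfig, KineticsError,
                       extract_features, features_to_frame)
from .synth import (CohortDataset, GeneratorConfig, ImagingConfig, SynthError,
                    generate_cohort, generate_image_stack)
from .stats import (closure_frequency, pearson_pairwise, plot_correlation_heatmap,
                    subgroup_by_iss, summarize_cohort, welch_ttest)
from .traces import SHEAR_SETTINGS, read_traces_csv, write_traces_csv

log = logging.getLogger("hemoflow")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """Raised for unusable run configurations or missing stage inputs."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    imaging: ImagingConfig = field(default_factory=lambda: ImagingConfig(
        frame_interval_s=30.0, roi_shape=(48, 120), noise_sd=20.0))
    n_image_patients: int = 2        # per group; 0 disables image rendering
    stats_fdr: bool = False
    heatmap: bool = False
    force: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        # run seed is authoritative for every stage
        self.generator = replace(self.generator, seed=int(self.seed))


def load_run_config(path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file; top-level keys mirror the dataclass."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, cls in (("generator", GeneratorConfig), ("kinetics", KineticsConfig),
                     ("imaging", ImagingConfig)):
        if key in raw:
            kwargs[key] = cls(**raw.pop(key))
    kwargs.update(raw)
    kwargs.update(overrides)
    if "out_dir" not in kwargs:
        raise PipelineError("config must provide out_dir")
    return RunConfig(**kwargs)


def _setup_logging(run_dir: Path, level: str) -> None:
    log.setLevel(level.upper())
    log.handlers = [logging.StreamHandler()]
    fh = logging.FileHandler(run_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _features_wide(features: pd.DataFrame) -> pd.DataFrame:
    """Per-patient wide table: <shear>_bt, <shear>_growth_rate, ..."""
    wide = pd.DataFrame(index=pd.Index(sorted(features["patient_id"].unique()),
                                       name="patient_id"))
    renames = {"bleeding_time_s": "bt", "growth_rate_um2_s": "growth_rate",
               "lag_time_s": "lag_time", "max_area_um2": "max_area",
               "max_mfi_fold_change": "mfi_fold_change"}
    for shear, sub in features.groupby("shear"):
        sub = sub.set_index("patient_id")
        for col, short in renames.items():
            wide[f"{shear}_{short}"] = pd.to_numeric(sub[col], errors="coerce")
    return wide


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    run_dir = config.out_dir
    if run_dir.exists() and any(run_dir.iterdir()):
        if not config.force:
            raise PipelineError(
                f"run directory {run_dir} is not empty; pass force to overwrite")
        shutil.rmtree(run_dir)
    for sub in ("cohort", "traces", "images", "features", "stats"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir, config.log_level)

    provenance = {
        "seed": int(config.seed),
        "config_hash": config.generator.config_hash(),
        "package_version": __version__,
        "n_trauma": config.generator.n_trauma,
        "n_control": config.generator.n_control,
    }
    _write_json(provenance, run_dir / "provenance.json")

    # --- simulate -----------------------------------------------------------
    log.info("simulate: n_trauma=%d n_control=%d seed=%d",
             config.generator.n_trauma, config.generator.n_control, config.seed)
    cohort = generate_cohort(config.generator)
    cohort.patients.to_csv(run_dir / "cohort" / "covariates.csv",
                           float_format=_FLOAT_FMT)
    cohort.ground_truth.to_csv(run_dir / "cohort" / "ground_truth.csv",
                               index=False, float_format=_FLOAT_FMT)
    all_traces = [cohort.traces[k] for k in sorted(cohort.traces)]
    write_traces_csv(all_traces, run_dir / "traces" / "traces.csv")

    # --- images (optional subset) ------------------------------------------
    if config.n_image_patients > 0 and len(cohort.patients):
        img_rng = np.random.default_rng([int(config.seed), 1])
        subset = (cohort.patients.groupby("group").head(config.n_image_patients)
                  .index.tolist())
        for pid in subset:
            for shear in config.generator.shear_settings:
                trace = cohort.traces.get((pid, shear))
                if trace is None:
                    continue
                try:
                    stack = generate_image_stack(trace, config.imaging, img_rng)
                except SynthError as err:
                    log.warning("images: skipping %s/%s: %s", pid, shear, err)
                    continue
                base = run_dir / "images" / f"{pid}_{shear}"
                write_stack_tiff(stack, base.with_suffix(".tif"))
                _write_json({"patient_id": pid, "shear": shear,
                             "truth_areas_um2": stack.truth_areas_um2.tolist(),
                             "timestamps_s": stack.timestamps_s.tolist(),
                             **trace.ground_truth},
                            base.with_suffix(".json"))
        log.info("images: rendered %d patients x %d shears", len(subset),
                 len(config.generator.shear_settings))

        # --- quantify -------------------------------------------------------
        quantified = []
        for tif in sorted((run_dir / "images").glob("*.tif")):
            quantified.append(stack_to_trace(read_stack_tiff(tif)))
        if quantified:
            write_traces_csv(quantified, run_dir / "traces" / "quantified_traces.csv")

    # --- kinetics -----------------------------------------------------------
    feats, rejected = [], []
    for key in sorted(cohort.traces):
        try:
            feats.append(extract_features(cohort.traces[key], config.kinetics))
        except KineticsError as err:
            rejected.append({"patient_id": key[0], "shear": key[1],
                             "reason": str(err)})
    features = features_to_frame(feats)
    features.to_csv(run_dir / "features" / "features.csv", index=False,
                    float_format=_FLOAT_FMT)
    if rejected:
        _write_json(rejected, run_dir / "features" / "rejected.json")
        log.warning("kinetics: rejected %d traces", len(rejected))

    # --- stats --------------------------------------------------------------
    report: dict = {"provenance": provenance, "groups": {}}
    comparisons = {}
    merged = features.merge(cohort.patients[["group"]], left_on="patient_id",
                            right_index=True)
    for shear in config.generator.shear_settings:
        sub = merged[merged["shear"] == shear]
        for group, gsub in sub.groupby("group"):
            cf = closure_frequency(gsub)
            report["groups"].setdefault(group, {})[shear] = {
                "n": int(len(gsub)),
                "mean_bleeding_time_s": float(gsub["bleeding_time_s"].mean()),
                "sd_bleeding_time_s": float(gsub["bleeding_time_s"].std(ddof=1))
                if len(gsub) > 1 else None,
                "closure_percent": cf.percent,
                "n_closed": cf.n_closed,
            }
        tr = sub[sub["group"] == "trauma"]["bleeding_time_s"]
        co = sub[sub["group"] == "control"]["bleeding_time_s"]
        if len(tr) >= 2 and len(co) >= 2:
            comparisons[f"bleeding_time_{shear}"] = welch_ttest(
                tr, co, labels=("trauma", "control")).to_dict()

    trauma_cov = cohort.patients[cohort.patients["group"] == "trauma"]
    if len(trauma_cov) >= 3:
        wide = _features_wide(features[features["patient_id"].isin(trauma_cov.index)])
        corr_table = trauma_cov.drop(columns=["group"]).join(wide)
        pairs = pearson_pairwise(corr_table, fdr=config.stats_fdr)
        pairs.to_csv(run_dir / "stats" / "correlations.csv", index=False,
                     float_format=_FLOAT_FMT)
        if config.heatmap:
            plot_correlation_heatmap(pairs, run_dir / "stats" /
                                     "correlation_heatmap.png")
        if "iss" in trauma_cov.columns:
            for shear, cmp_ in subgroup_by_iss(cohort.patients, features).items():
                comparisons[f"iss_subgroup_{shear}"] = cmp_.to_dict()
    _write_json(comparisons, run_dir / "stats" / "comparisons.json")

    summary = summarize_cohort(cohort.patients, features)
    summary["demographics"].to_csv(run_dir / "stats" / "summary_demographics.csv",
                                   index=False, float_format=_FLOAT_FMT)
    summary["features"].to_csv(run_dir / "stats" / "summary_features.csv",
                               index=False, float_format=_FLOAT_FMT)

    report["comparisons"] = comparisons
    report["artifacts"] = {
        "covariates": "cohort/covariates.csv",
        "ground_truth": "cohort/ground_truth.csv",
        "traces": "traces/traces.csv",
        "features": "features/features.csv",
        "correlations": "stats/correlations.csv",
        "comparisons": "stats/comparisons.json",
    }
    _write_json(report, run_dir / "report.json")
    log.info("run complete: %s", run_dir)
    return run_dir


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(trace_csv=None, covariate_csv=None, tiff_paths=()) -> list:
    """Schema/sanity checks; returns a list of violation dicts (never raises).

    Each violation has ``severity`` ("error" or "warning"), ``file``,
    ``message`` and, where applicable, ``row``.
    """
    findings: list = []

    def add(severity, file, message, row=None):
        item = {"severity": severity, "file": str(file), "message": message}
        if row is not None:
            item["row"] = int(row)
        findings.append(item)

    if trace_csv is not None:
        try:
            df = pd.read_csv(trace_csv)
        except Exception as err:                      # noqa: BLE001
            add("error", trace_csv, f"unreadable: {err}")
            df = None
        if df is not None:
            from .traces import TRACE_COLUMNS
            for col in TRACE_COLUMNS:
                if col not in df.columns:
                    add("error", trace_csv, f"missing column {col}")
            if {"patient_id", "shear", "t_s"} <= set(df.columns):
                for (pid, shear), grp in df.groupby(["patient_id", "shear"]):
                    t = grp["t_s"].to_numpy(dtype=float)
                    bad = np.nonzero(np.diff(t) <= 0)[0]
                    if bad.size:
                        add("error", trace_csv,
                            f"non-monotone timestamps for ({pid}, {shear})",
                            row=grp.index[bad[0] + 1])
                    if shear not in SHEAR_SETTINGS:
                        add("error", trace_csv, f"unknown shear setting {shear!r}")
                if "area_um2" in df.columns and (pd.to_numeric(
                        df["area_um2"], errors="coerce") < 0).any():
                    add("warning", trace_csv, "negative areas present")
                if "flow" in df.columns:
                    fl = pd.to_numeric(df["flow"], errors="coerce")
                    if ((fl < 0) | (fl > 1)).any():
                        add("error", trace_csv, "flow outside [0, 1]")

    if covariate_csv is not None:
        try:
            cov = pd.read_csv(covariate_csv)
        except Exception as err:                      # noqa: BLE001
            add("error", covariate_csv, f"unreadable: {err}")
            cov = None
        if cov is not None:
            if "patient_id" not in cov.columns:
                add("error", covariate_csv, "missing patient_id column")
            elif cov["patient_id"].duplicated().any():
                add("error", covariate_csv, "duplicate patient_id values")
            known = {"patient_id", "group"} | {
                s.name for s in GeneratorConfig().covariates}
            for col in cov.columns:
                if col not in known:
                    add("warning", covariate_csv, f"unknown covariate column {col}")

    for path in tiff_paths:
        try:
            stack = read_stack_tiff(path)
        except Exception as err:                      # noqa: BLE001
            add("error", path, f"unreadable TIFF: {err}")
            continue
        if np.any(np.diff(stack.timestamps_s) <= 0):
            add("error", path, "non-monotone frame timestamps")
    return findings
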