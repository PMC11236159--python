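"""Assay trace container and the shared long-format CSV dialect.

An :class:`AssayTrace` is the central in-memory object of the pipeline: one
microfluidic assay's time series of clot surface area, platelet fluorescence
intensity, and normalized outlet flow, recorded at a fixed shear setting
(venous-like ~150 1/s or arterial-like ~3500 1/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

VENOUS = "venous"
ARTERIAL = "arterial"
SHEAR_SETTINGS = (VENOUS, ARTERIAL)

#: nominal wall shear rates (1/s) for the two perfusion settings
SHEAR_RATES = {VENOUS: 150.0, ARTERIAL: 3500.0}

TRACE_COLUMNS = ["patient_id", "shear", "t_s", "area_um2", "platelet_intensity", "flow"]


class TraceError(ValueError):
    """Raised when a trace violates the container's invariants."""


@dataclass
class AssayTrace:
    """Time series of one microfluidic hemostasis assay.

    Parameters
    ----------
    time:
        Seconds since perfusion start; strictly increasing, ``time[0] == 0``.
    area:
        Clot surface area in the injury-site ROI (um^2), clipped at 0.
    flow:
        Normalized outlet flow in [0, 1]; ``None`` when the source (e.g. an
        image stack) carries no flow readout.
    platelet_intensity:
        Total platelet-label fluorescence (a.u.); ``None`` when the assay was
        run without the fluorescence channel.
    shear_setting:
        ``"venous"`` or ``"arterial"``.
    ground_truth:
        Generator sidecar (dict) for synthetic traces; absent for measured
        ones. Used only by recovery tests and provenance, never by analysis.
    """

    time: np.ndarray
    area: np.ndarray
    shear_setting: str
    flow: Optional[np.ndarray] = None
    platelet_intensity: Optional[np.ndarray] = None
    patient_id: Optional[str] = None
    early_stop: bool = False
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.flow is not None:
            self.flow = np.asarray(self.flow, dtype=float)
        if self.platelet_intensity is not None:
            self.platelet_intensity = np.asarray(self.platelet_intensity, dtype=float)
        n = self.time.size
        if n < 2:
            raise TraceError("trace needs at least two samples")
        if self.time[0] != 0.0:
            raise TraceError("time axis must start at perfusion start (t=0)")
        if np.any(np.diff(self.time) <= 0):
            raise TraceError("timestamps must be strictly increasing")
        for name, series in (("area", self.area),
                             ("flow", self.flow),
                             ("platelet_intensity", self.platelet_intensity)):
            if series is not None and series.size != n:
                raise TraceError(f"{name} length {series.size} != time length {n}")
        if self.shear_setting not in SHEAR_SETTINGS:
            raise TraceError(f"unknown shear setting {self.shear_setting!r}")
        self.area = np.clip(self.area, 0.0, None)

    @property
    def duration(self) -> float:
        return float(self.time[-1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format rows for this trace (shared CSV dialect)."""
        n = self.time.size
        return pd.DataFrame({
            "patient_id": [self.patient_id or ""] * n,
            "shear": [self.shear_setting] * n,
            "t_s": self.time,
            "area_um2": self.area,
            "platelet_intensity": (self.platelet_intensity
                                   if self.platelet_intensity is not None
                                   else [""] * n),
            "flow": self.flow if self.flow is not None else [""] * n,
        })


def traces_to_frame(traces) -> pd.DataFrame:
    """Concatenate traces into one long-format table."""
    return pd.concat([t.to_frame() for t in traces], ignore_index=True)


def write_traces_csv(traces, path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.10g")


def read_traces_csv(path) -> list[AssayTrace]:
    """Read the long-format dialect back into AssayTrace objects.

    Grouped by (patient_id, shear); empty intensity/flow cells become None
    series for the whole trace.
    """
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(f"trace CSV missing columns: {missing}")
    out = []
    for (pid, shear), grp in df.groupby(["patient_id", "shear"], sort=True):
        grp = grp.sort_values("t_s")
        intensity = grp["platelet_intensity"].to_numpy(dtype=float)
        flow = grp["flow"].to_numpy(dtype=float)
        out.append(AssayTrace(
            time=grp["t_s"].to_numpy(dtype=float),
            area=grp["area_um2"].to_numpy(dtype=float),
            shear_setting=str(shear),
            flow=None if np.all(np.isnan(flow)) else flow,
            platelet_intensity=(None if np.all(np.isnan(intensity)) else intensity),
            patient_id=str(pid) if pid else None,
        ))
    return out
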