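"""Laminar Newtonian flow in a rectangular microchannel.

Exact Fourier-series solution for pressure-driven (Poiseuille) flow in a
straight duct of rectangular cross-section with no-slip walls, used to
convert between inlet volumetric flow rate and the initial wall shear rate
at the native lumen, plus the steady-state co-flow dilution used for sample
recalcification.

For a duct of width ``w`` (long side, coordinate y in [-w/2, w/2]) and
height ``h`` (z in [0, h]) under pressure gradient G = dp/dx, the axial
velocity is

    u(y, z) = (4 G h^2 / (pi^3 mu)) * sum_{n odd} (1/n^3)
              [1 - cosh(n pi y / h)/cosh(n pi w / (2 h))] sin(n pi z / h)

with flow rate

    Q = (G h^3 w / (12 mu)) [1 - (192 h)/(pi^5 w) sum_{n odd} tanh(n pi w/(2h))/n^5]

and wall shear rate at the midpoint of the long wall (y=0, z=0)

    du/dz = (4 G h / (pi^2 mu)) [pi^2/8 - sum_{n odd} sech(n pi w/(2h))/n^2].

The shear-rate-to-flow ratio is geometric (independent of viscosity and of
G), so a single unit solution converts both ways. In the wide-channel limit
w/h -> inf the ratio tends to the parallel-plate value 6 Q / (w h^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

#: um^3/s per uL/min
_UL_MIN_TO_UM3_S = 1.0e9 / 60.0

# series tail is bounded by the first omitted sech/tanh term; this many odd
# terms puts the relative truncation error far below the 1e-8 requirement
# for any aspect ratio >= 1
_DEFAULT_TERMS = 400
_TRUNCATION_TOL = 1e-8


class GeometryError(ValueError):
    """Raised for non-physical channel dimensions."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular duct cross-section, dimensions in micrometres.

    The assay device is 50 um high throughout, with a 150 um wide native
    lumen and a 50 um wide injury site; only the native lumen enters the
    flow-rate/shear conversion.
    """

    width_um: float
    height_um: float
    length_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise GeometryError("channel dimensions must be positive")
        if self.length_um is not None and self.length_um <= 0:
            raise GeometryError("channel length must be positive")

    @property
    def aspect_ratio(self) -> float:
        """Long side over short side (>= 1)."""
        return max(self.width_um, self.height_um) / min(self.width_um, self.height_um)


#: native lumen of the assay device
NATIVE_LUMEN = ChannelGeometry(width_um=150.0, height_um=50.0)
#: injury-site channel of the assay device
INJURY_SITE = ChannelGeometry(width_um=50.0, height_um=50.0)


@dataclass(frozen=True)
class FluidModel:
    """Newtonian fluid; whole blood approximated at 3.5 cP."""

    viscosity_cP: float = 3.5

    def __post_init__(self) -> None:
        if self.viscosity_cP <= 0:
            raise GeometryError("viscosity must be positive")


@dataclass(frozen=True)
class FlowSolution:
    """One converted operating point of the duct."""

    flow_rate_ul_min: float
    wall_shear_rate_per_s: float
    series_terms: int
    truncation_residual: float

    def to_dict(self) -> dict:
        return {
            "flow_rate_ul_min": self.flow_rate_ul_min,
            "wall_shear_rate_per_s": self.wall_shear_rate_per_s,
            "series_terms": self.series_terms,
            "truncation_residual": self.truncation_residual,
        }


def _unit_solution(geom: ChannelGeometry, nterms: int = _DEFAULT_TERMS):
    """Q and wall shear per unit (G/mu), lengths in um.

    Returns (Q_unit, shear_unit, terms, residual). Shear is evaluated at the
    midpoint of the long wall; for width < height the roles of the two sides
    are swapped (the solution is symmetric under transposition).
    """
    w = max(geom.width_um, geom.height_um)
    h = min(geom.width_um, geom.height_um)
    n = np.arange(1, 2 * nterms, 2, dtype=float)
    x = n * math.pi * w / (2.0 * h)
    # sech computed stably: 2 e^-x / (1 + e^-2x)
    sech = 2.0 * np.exp(-x) / (1.0 + np.exp(-2.0 * x))
    tanh = np.tanh(x)

    q_series = np.sum(tanh / n**5)
    Q = (h**3 * w / 12.0) * (1.0 - (192.0 / math.pi**5) * (h / w) * q_series)

    s_series = np.sum(sech / n**2)
    shear = (4.0 * h / math.pi**2) * (math.pi**2 / 8.0 - s_series)

    # tail bounds: remaining tanh/n^5 < integral tail; remaining sech/n^2
    # decays exponentially -- bound both by the first omitted term
    n_next = 2.0 * nterms + 1.0
    tail_q = (192.0 / math.pi**5) * (h / w) / (4.0 * (n_next - 1.0) ** 4)
    tail_s = (4.0 * h / math.pi**2) * math.exp(-n_next * math.pi * w / (2.0 * h)) / n_next**2
    residual = max(tail_q / max(Q / (h**3 * w / 12.0), 1e-300),
                   tail_s / max(shear, 1e-300))
    if residual > _TRUNCATION_TOL:
        warnings.warn(f"series truncation residual {residual:.2e} above "
                      f"{_TRUNCATION_TOL:.0e}", RuntimeWarning, stacklevel=2)
    return Q, shear, nterms, residual


def shear_per_flow(geom: ChannelGeometry) -> float:
    """Wall shear rate (1/s) per unit flow rate (uL/min): geometric ratio."""
    Q_unit, shear_unit, _, _ = _unit_solution(geom)
    return shear_unit / Q_unit * _UL_MIN_TO_UM3_S


def wall_shear_from_flow(geom: ChannelGeometry, flow_rate_ul_min: float) -> float:
    """Wall shear rate (1/s) at the long-wall midpoint for a given flow rate.

    Linear in flow rate and independent of viscosity.
    """
    if flow_rate_ul_min < 0:
        raise ValueError("flow rate must be non-negative")
    return shear_per_flow(geom) * flow_rate_ul_min


def flow_for_target_shear(geom: ChannelGeometry, target_shear_per_s: float) -> float:
    """Inlet flow rate (uL/min) producing the target wall shear rate (1/s)."""
    if target_shear_per_s <= 0:
        raise ValueError("target shear rate must be positive")
    return target_shear_per_s / shear_per_flow(geom)


def solve_operating_point(geom: ChannelGeometry,
                          flow_rate_ul_min: Optional[float] = None,
                          target_shear_per_s: Optional[float] = None) -> FlowSolution:
    """Build a :class:`FlowSolution` from either a flow rate or a shear target."""
    if (flow_rate_ul_min is None) == (target_shear_per_s is None):
        raise ValueError("give exactly one of flow rate or target shear")
    Q_unit, shear_unit, terms, residual = _unit_solution(geom)
    ratio = shear_unit / Q_unit * _UL_MIN_TO_UM3_S
    if flow_rate_ul_min is None:
        flow_rate_ul_min = target_shear_per_s / ratio
    return FlowSolution(
        flow_rate_ul_min=float(flow_rate_ul_min),
        wall_shear_rate_per_s=float(ratio * flow_rate_ul_min),
        series_terms=terms,
        truncation_residual=float(residual),
    )


def velocity_field(geom: ChannelGeometry, flow_rate_ul_min: float,
                   ny: int = 101, nz: int = 51) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axial velocity u(y, z) in um/s on a grid, scaled to the given flow rate.

    Returns (y, z, u) with y along the long side in [-w/2, w/2] and z along
    the short side in [0, h]. Used for flow-conservation and no-slip checks.
    """
    w = max(geom.width_um, geom.height_um)
    h = min(geom.width_um, geom.height_um)
    y = np.linspace(-w / 2.0, w / 2.0, ny)
    z = np.linspace(0.0, h, nz)
    n = np.arange(1, 2 * _DEFAULT_TERMS, 2, dtype=float)
    # u per unit G/mu
    arg = np.minimum(n[:, None] * math.pi * np.abs(y)[None, :] / h, 700.0)
    denom_arg = np.minimum(n * math.pi * w / (2.0 * h), 700.0)
    ratio = np.cosh(arg) / np.cosh(denom_arg)[:, None]          # (n, ny)
    sin_z = np.sin(n[:, None] * math.pi * z[None, :] / h)       # (n, nz)
    coef = (4.0 * h**2 / math.pi**3) / n**3
    u_unit = np.einsum("n,ny,nz->yz", coef, 1.0 - ratio, sin_z)
    Q_unit, _, _, _ = _unit_solution(geom)
    scale = flow_rate_ul_min * _UL_MIN_TO_UM3_S / Q_unit
    return y, z, u_unit * scale


def coflow_final_concentration(stock_mM: float, flow_ratio: float,
                               target_band_mM: tuple[float, float] = (10.0, 15.0)) -> float:
    """Steady-state concentration after merging a co-flow with the sample.

    Perfect-mixing mass balance: a co-flow at ``flow_ratio`` times the sample
    flow rate carrying ``stock_mM`` dilutes to ``stock * r / (1 + r)``.
    Warns when the result falls outside the recalcification target band
    (default 10-15 mM for the 100 mM CaCl2 co-flow at 10%).
    """
    if stock_mM < 0 or flow_ratio < 0:
        raise ValueError("stock concentration and flow ratio must be non-negative")
    final = stock_mM * flow_ratio / (1.0 + flow_ratio) if flow_ratio > 0 else 0.0
    lo, hi = target_band_mM
    if not (lo <= final <= hi):
        warnings.warn(
            f"co-flow final concentration {final:.3g} mM outside target band "
            f"{lo:g}-{hi:g} mM", UserWarning, stacklevel=2)
    return final
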