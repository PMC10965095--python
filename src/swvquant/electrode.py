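"""Double-layer capacitance (Cdl) estimation from scan-rate-series CV.

At a non-faradaic potential (0.05 V by default) the current is purely
capacitive, so half the anodic–cathodic current-density difference equals
Cdl times the scan rate.  Cdl is the slope of |j_a − j_c| / 2 against scan
rate (converted to V/s), reported in µF/cm².  The line is fitted with an
intercept by default — real cells carry non-faradaic offsets — but can be
forced through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError, PairingError, RangeError
from .io import Voltammogram

__all__ = ["CdlMeasurement", "CdlEstimate", "extract_cdl_point", "estimate_cdl"]


@dataclass(frozen=True)
class CdlMeasurement:
    """Capacitive current densities of one anodic/cathodic pair."""

    scan_rate: float   # mV/s
    j_a: float         # anodic current density, µA/cm²
    j_c: float         # cathodic current density, µA/cm²

    @property
    def half_diff(self) -> float:
        """|j_a − j_c| / 2 in µA/cm²."""
        return abs(self.j_a - self.j_c) / 2.0


@dataclass(frozen=True)
class CdlEstimate:
    """Slope fit of half_diff vs scan rate."""

    cdl: float             # µF/cm²
    intercept: float       # µA/cm²
    residual_norm: float   # µA/cm²

    @property
    def physical(self) -> bool:
        """A negative capacitance is non-physical and flags a bad fit."""
        return self.cdl >= 0


def _interp_current(v: Voltammogram, potential: float) -> float:
    lo, hi = v.potential_range
    if not lo <= potential <= hi:
        raise RangeError(
            f"non-faradaic point {potential:g} V outside sweep [{lo:g}, {hi:g}]"
        )
    return float(np.interp(potential, v.potentials, v.currents))


def extract_cdl_point(
    anodic: Voltammogram, cathodic: Voltammogram, e_nf: float = 0.05
) -> CdlMeasurement:
    """Interpolate both branches at the non-faradaic point ``e_nf`` (V)."""
    if anodic.scan_rate != cathodic.scan_rate:
        raise PairingError(
            f"scan-rate mismatch between branches: "
            f"{anodic.scan_rate} vs {cathodic.scan_rate} mV/s"
        )
    if anodic.scan_rate is None:
        raise PairingError("CV branches must carry a scan_rate")
    return CdlMeasurement(
        scan_rate=float(anodic.scan_rate),
        j_a=_interp_current(anodic, e_nf),
        j_c=_interp_current(cathodic, e_nf),
    )


def estimate_cdl(
    points: Sequence[CdlMeasurement], *, fit_intercept: bool = True
) -> CdlEstimate:
    """Least-squares line of half_diff against scan rate (V/s).

    The slope has units µA/cm² per V/s = µF/cm².
    """
    if len(points) < 2:
        raise InsufficientDataError("Cdl fit needs >= 2 measurements")
    nu = np.array([p.scan_rate for p in points]) / 1000.0  # V/s
    y = np.array([p.half_diff for p in points])
    if np.ptp(nu) == 0:
        raise InsufficientDataError("all scan rates equal; slope undefined")
    if fit_intercept:
        design = np.column_stack([np.ones_like(nu), nu])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, slope = float(coef[0]), float(coef[1])
    else:
        slope = float(np.dot(nu, y) / np.dot(nu, nu))
        intercept = 0.0
    resid = y - (intercept + slope * nu)
    return CdlEstimate(
        cdl=slope, intercept=intercept, residual_norm=float(np.linalg.norm(resid))
    )
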