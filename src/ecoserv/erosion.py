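"""Potential soil loss via the Universal Soil Loss Equation.

Per-cell loss rate is the five-factor product A = R·K·LS·C·P, with the
rainfall erosivity R estimated from monthly and annual precipitation by the
empirical power-sum formula

    R = 1.2157 · Σ_{i=1..12} 10^{1.5·lg(P_i²/P) − 0.0818}
      = 1.2157 · 10^{−0.0818} · Σ_i (P_i²/P)^{1.5},

so R is homogeneous of degree 1.5 in the precipitation field.  Months with
zero precipitation contribute zero, and an all-dry year gives R = 0.  R's
unit is treated as opaque-but-consistent; totals are reported in 10⁴ t with
the loss rate read as t/hm².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CLASS_NAMES, HM2_PER_KM2, LandUseRaster, SoilTerrainStack
from .params import UsleClassFactors, class_lookup_grid

log = logging.getLogger(__name__)

_EROSIVITY_CONST = 1.2157 * 10 ** (-0.0818)


@dataclass
class ErosionResult:
    loss_t: np.ndarray             # per-cell potential loss (t)
    class_totals_1e4t: pd.Series   # per-class totals (10⁴ t)
    total_1e4t: float


def rainfall_erosivity(monthly_mm, annual_mm=None):
    """Rainfall erosivity R from 12 monthly precipitation values (or grids).

    ``monthly_mm`` is a length-12 sequence (scalar months) or a (12, …) array.
    The annual total is recomputed internally; if a caller-supplied
    ``annual_mm`` disagrees by more than 0.1% a warning is logged and the
    recomputed value is used.
    """
    monthly = np.asarray(monthly_mm, dtype=float)
    if monthly.shape[0] != 12:
        raise ValueError("expected 12 monthly precipitation values")
    if np.any(monthly < 0):
        raise ValueError("monthly precipitation must be non-negative")
    annual = monthly.sum(axis=0)
    if annual_mm is not None:
        supplied = np.asarray(annual_mm, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(supplied - annual) / np.where(annual > 0, annual, 1.0)
        if np.any(rel > 1e-3):
            log.warning("annual precipitation differs from monthly sum by >0.1%%; "
                        "using the recomputed sum")
    annual_safe = np.where(annual > 0, annual, 1.0)
    terms = (monthly**2 / annual_safe) ** 1.5
    r = _EROSIVITY_CONST * terms.sum(axis=0)
    r = np.where(annual > 0, r, 0.0)
    return float(r) if np.ndim(annual) == 0 else r


def usle(lu: LandUseRaster, erosivity: np.ndarray, soil: SoilTerrainStack,
         factors: UsleClassFactors) -> ErosionResult:
    """Per-cell potential loss R·K·LS·C·P and per-class totals."""
    erosivity = np.asarray(erosivity, dtype=float)
    if erosivity.shape != lu.codes.shape:
        raise ValueError("erosivity grid not co-registered with land use")
    if np.any(erosivity < 0):
        raise ValueError("erosivity must be non-negative")
    present = {int(c) for c in np.unique(lu.codes[lu.valid])}
    for code in present:
        name = CLASS_NAMES[code]
        if name not in factors.c_factor or name not in factors.p_factor:
            raise KeyError(f"no USLE factors for class {name!r}")
    c = class_lookup_grid(lu.codes, factors.c_factor)
    p = class_lookup_grid(lu.codes, factors.p_factor)
    rate = erosivity * soil.k_factor * soil.ls_factor * c * p  # t/hm²
    rate = np.where(lu.valid, rate, 0.0)
    loss = rate * lu.cell_area_km2 * HM2_PER_KM2  # t per cell
    totals = pd.Series({CLASS_NAMES[code]: float(loss[lu.codes == code].sum()) / 1e4
                        for code in sorted(present)})
    totals = totals.reindex(list(CLASS_NAMES.values()), fill_value=0.0)
    return ErosionResult(loss, totals, float(totals.sum()))


def ls_from_slope(slope_deg: np.ndarray, slope_length_m: float = 22.13,
                  m: float = 0.5) -> np.ndarray:
    """Convenience LS from a slope grid (length-exponent form with the
    McCool S relation); the pipeline itself consumes LS as an input raster."""
    theta = np.deg2rad(np.asarray(slope_deg, dtype=float))
    s = 65.41 * np.sin(theta) ** 2 + 4.56 * np.sin(theta) + 0.065
    return (slope_length_m / 22.13) ** m * s
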