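"""Habitat quality from distance-decayed threat influence.

Quality of cell x under land-use class j is

    Q_xj = H_j · [1 − D_xj^z / (D_xj^z + k^z)],

where H_j is the class's habitat suitability, D_xj the degradation degree,
z a sharpness exponent (default 2.5) and k the half-saturation constant,
set by default to half the realized maximum degradation so that the worst
cell loses just under its full suitability.

Degradation aggregates threat influence as

    D_x = Σ_r (w_r / Σw) · i_r(x) · S_{j(x),r},

with i_r(x) the distance-decayed influence of the *nearest* cell of threat r
(max-combine over source cells — the nearest source dominates under any
monotone decay), either linear (1 − d/d_max, zero beyond d_max) or
exponential (exp(−2.99·d/d_max)).  A sum-over-cells mode is available for
sensitivity analysis but unbounded on dense threat maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import CLASS_NAMES, LandUseRaster, NAME_TO_CODE, RegionPartition

log = logging.getLogger(__name__)


@dataclass
class HabitatParams:
    """Saturation exponent and optional explicit half-saturation constant."""

    z: float = 2.5
    k_override: float | None = None
    combine: str = "max"  # per-threat combine over source cells: max | sum

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("exponent z must be positive")
        if self.k_override is not None and self.k_override <= 0:
            raise ValueError("half-saturation override must be positive")
        if self.combine not in ("max", "sum"):
            raise ValueError("combine must be 'max' or 'sum'")


@dataclass
class HabitatResult:
    degradation: np.ndarray
    quality: np.ndarray
    k: float
    class_sums: pd.Series       # Σ cell Q per class
    mean_quality: float         # domain mean over valid cells


def threat_influence(threat_mask: np.ndarray, d_max_km: float, decay: str,
                     cell_size_km: float = 1.0, combine: str = "max") -> np.ndarray:
    """Per-cell influence in [0, 1] of one threat's source cells.

    ``max`` combine uses the nearest source (Euclidean distance transform);
    ``sum`` accumulates the decayed influence of every source cell, clipped
    to 1 for linear decay only after summation is *not* applied — callers
    using sum mode accept unbounded stacking.
    """
    if d_max_km <= 0:
        raise ValueError("maximum impact distance must be positive")
    mask = np.asarray(threat_mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape)
    if combine == "max":
        d = ndimage.distance_transform_edt(~mask) * cell_size_km
        return _decay(d, d_max_km, decay)
    rows, cols = np.nonzero(mask)
    ii, jj = np.indices(mask.shape)
    out = np.zeros(mask.shape)
    for r, c in zip(rows, cols):
        d = np.hypot(ii - r, jj - c) * cell_size_km
        out += _decay(d, d_max_km, decay)
    return out


def _decay(d: np.ndarray, d_max: float, kind: str) -> np.ndarray:
    if kind == "linear":
        return np.clip(1.0 - d / d_max, 0.0, 1.0)
    if kind == "exponential":
        return np.exp(-(2.99 / d_max) * d)
    raise ValueError(f"unknown decay kind {kind!r}")


def degradation(lu: LandUseRaster, threats, sens) -> np.ndarray:
    """Habitat degradation degree D per cell (weighted sum across threats)."""
    present = {CLASS_NAMES[int(c)] for c in np.unique(lu.codes[lu.valid])}
    missing = present - set(sens.table.index)
    if missing:
        raise KeyError(f"classes without sensitivity rows: {sorted(missing)}")
    w_total = float(threats.table.weight.sum())
    d = np.zeros(lu.codes.shape)
    for threat_name, row in threats.table.iterrows():
        mask = lu.mask(NAME_TO_CODE[threat_name])
        infl = threat_influence(mask, float(row.max_distance_km), row.decay,
                                lu.cell_size_km)
        s_grid = np.zeros(lu.codes.shape)
        for cls in present:
            s_grid[lu.codes == NAME_TO_CODE[cls]] = float(sens.table.loc[cls, threat_name])
        d += (float(row.weight) / w_total) * infl * s_grid
    d[~lu.valid] = 0.0
    return d


def habitat_quality(d_grid: np.ndarray, lu: LandUseRaster, sens,
                    params: HabitatParams | None = None) -> HabitatResult:
    """Quality raster from a degradation raster, with the k-from-max rule."""
    params = params or HabitatParams()
    d = np.asarray(d_grid, dtype=float)
    if np.any(d < 0):
        raise ValueError("degradation must be non-negative")
    if params.k_override is not None:
        k = params.k_override
    else:
        d_max = float(d[lu.valid].max()) if lu.valid.any() else 0.0
        if d_max == 0.0:
            log.warning("zero degradation everywhere and no k override; Q = H_j")
            k = 1.0  # inert: D^z = 0 regardless
        else:
            k = 0.5 * d_max
    h = np.zeros(lu.codes.shape)
    for cls in sens.table.index:
        h[lu.codes == NAME_TO_CODE[cls]] = sens.suitability(cls)
    with np.errstate(divide="ignore", invalid="ignore"):
        dz = d**params.z
        q = h * (1.0 - dz / (dz + k**params.z))
    q = np.where(lu.valid, q, 0.0)
    present = sorted(int(c) for c in np.unique(lu.codes[lu.valid]))
    sums = pd.Series({CLASS_NAMES[c]: float(q[lu.codes == c].sum()) for c in present})
    sums = sums.reindex(list(CLASS_NAMES.values()), fill_value=0.0)
    mean_q = float(q[lu.valid].mean()) if lu.valid.any() else 0.0
    return HabitatResult(d, q, k, sums, mean_q)


def regional_mean_quality(result: HabitatResult, lu: LandUseRaster,
                          regions: RegionPartition) -> pd.Series:
    """Mean quality per region over valid cells."""
    out = {}
    for label in regions.labels:
        m = (regions.region_id == label) & lu.valid
        out[int(label)] = float(result.quality[m].mean()) if m.any() else np.nan
    return pd.Series(out, name="mean_quality")
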