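"""Annual water yield per cell under the Budyko–Fu framework.

Yield is precipitation minus actual evapotranspiration, Y(x) = P(x) − AET(x),
with AET given by the Fu/Zhang curve

    AET/P = 1 + PET/P − (1 + (PET/P)^ω)^(1/ω),    ω = Z·AWC/P + ω₀,

where PET = Kc(class)·ET0, AWC (mm) = PAWC × rooting depth, Z is the
seasonality constant (default 5.0) and ω₀ = 1.25 the empirical offset.  The
curve respects both limits: AET → 0 as PET → 0 and AET → P as PET/P → ∞, so
0 ≤ Y ≤ P cell-wise and the water balance Y + AET = P holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ClimateStack, LandUseRaster, SoilTerrainStack
from .params import WaterYieldParams, class_lookup_grid

#: mm over one km² in units of 10⁸ m³: 1 mm·km² = 10³ m³.
_MM_KM2_TO_1E8M3 = 1e3 / 1e8


@dataclass
class WaterYieldResult:
    aet_mm: np.ndarray
    yield_mm: np.ndarray
    class_volumes_1e8m3: pd.Series
    total_1e8m3: float


def budyko_aet(precip_mm, pet_mm, awc_mm, params: WaterYieldParams):
    """Actual evapotranspiration (mm) from the Fu curve; accepts scalars or grids.

    Cells with zero precipitation return AET 0.  Negative inputs are rejected.
    """
    p = np.asarray(precip_mm, dtype=float)
    pet = np.asarray(pet_mm, dtype=float)
    awc = np.asarray(awc_mm, dtype=float)
    if np.any(p < 0) or np.any(pet < 0) or np.any(awc < 0):
        raise ValueError("precipitation, PET and AWC must be non-negative")
    p_safe = np.where(p > 0, p, 1.0)
    omega = params.z_coeff * awc / p_safe + params.omega_offset
    phi = np.asarray(pet / p_safe)  # aridity index
    # (1 + φ^ω)^(1/ω): factor out φ when φ > 1 so φ^ω never overflows
    big = phi > 1.0
    phi_b = np.where(big, phi, 1.0)
    with np.errstate(over="ignore"):
        term = np.where(
            big,
            phi_b * (1.0 + phi_b**-omega) ** (1.0 / omega),
            (1.0 + np.where(big, 1.0, phi)**omega) ** (1.0 / omega))
    ratio = 1.0 + phi - term
    aet = np.clip(ratio, 0.0, 1.0) * p
    aet = np.where(p > 0, aet, 0.0)
    return float(aet) if np.isscalar(precip_mm) else aet


def water_yield(lu: LandUseRaster, climate: ClimateStack, soil: SoilTerrainStack,
                params: WaterYieldParams) -> WaterYieldResult:
    """Per-cell yield Y = P − AET and volumetric totals by class."""
    if climate.annual_precip.shape != lu.codes.shape:
        raise ValueError("climate grids not co-registered with land use")
    missing = set(np.unique(lu.codes[lu.valid]))
    from .grids import CLASS_NAMES
    names = {code: CLASS_NAMES[code] for code in missing}
    for code, name in names.items():
        if name not in params.kc or name not in params.root_depth_mm:
            raise KeyError(f"no water-yield parameters for class {name!r}")
    kc = class_lookup_grid(lu.codes, params.kc)
    root = class_lookup_grid(lu.codes, params.root_depth_mm)
    pet = kc * climate.annual_pet
    awc = soil.pawc * root
    aet = budyko_aet(climate.annual_precip, pet, awc, params)
    y = climate.annual_precip - aet
    y[~lu.valid] = 0.0
    aet = np.where(lu.valid, aet, 0.0)
    cell_vol = y * lu.cell_area_km2 * _MM_KM2_TO_1E8M3
    totals = pd.Series({name: float(cell_vol[lu.codes == code].sum())
                        for code, name in sorted(names.items())})
    totals = totals.reindex(list(CLASS_NAMES.values()), fill_value=0.0)
    return WaterYieldResult(aet, y, totals, float(totals.sum()))
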