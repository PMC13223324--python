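"""Food and raw-material supply valued by the equivalent-factor method.

Each land-use class carries two provisioning coefficients (food production
and raw-material production, Yuan/hm²/yr), expressible as dimensionless
equivalents times a regional unit value E0 (default 1,505.8 Yuan/hm², the
market value of one-seventh of the mean grain yield per hectare).  A class's
value is its area in hm² times the combined coefficient; built-up and unused
land carry zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import HM2_PER_KM2, LandUseRaster, RegionPartition
from .accounting import class_areas
from .params import EsvCoefficients, class_lookup_grid


@dataclass
class EsvResult:
    value_yuan: np.ndarray          # per-cell value (Yuan)
    class_totals_1e8yuan: pd.Series
    total_1e8yuan: float


def coefficients_from_equivalents(equivalents: pd.DataFrame,
                                  unit_value: float = 1505.8) -> pd.DataFrame:
    """Convert dimensionless per-class equivalents to Yuan/hm² coefficients."""
    eq = equivalents.astype(float)
    if (eq < 0).any().any():
        raise ValueError("equivalents must be non-negative")
    return eq * unit_value


def food_material_value(lu: LandUseRaster, coeffs: EsvCoefficients,
                        use_printed_combined: bool = False) -> EsvResult:
    """Per-cell and per-class food+raw-material value."""
    combined = coeffs.combined(use_printed=use_printed_combined)
    present = {c for c in pd.unique(lu.codes[lu.valid].ravel())}
    from .grids import CLASS_NAMES
    missing = {CLASS_NAMES[int(c)] for c in present} - set(combined.index)
    if missing:
        raise KeyError(f"classes without ESV coefficients: {sorted(missing)}")
    per_hm2 = class_lookup_grid(lu.codes, combined.to_dict())
    value = per_hm2 * lu.cell_area_km2 * HM2_PER_KM2
    value = np.where(lu.valid, value, 0.0)
    areas_hm2 = class_areas(lu) * HM2_PER_KM2
    totals = (areas_hm2 * combined.reindex(areas_hm2.index)) / 1e8
    return EsvResult(value, totals, float(totals.sum()))


def per_unit_area_value(result: EsvResult, lu: LandUseRaster,
                        regions: RegionPartition) -> pd.Series:
    """Per-region value density in 10⁴ Yuan/km² (a region of pure dry land
    sits at ≈ 18.8, the dry-land coefficient times 100 hm²/km² over 10⁴)."""
    out = {}
    for label in regions.labels:
        m = (regions.region_id == label) & lu.valid
        area_km2 = m.sum() * lu.cell_area_km2
        out[int(label)] = float(result.value_yuan[m].sum()) / area_km2 / 1e4 \
            if area_km2 > 0 else np.nan
    return pd.Series(out, name="value_1e4yuan_km2")
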