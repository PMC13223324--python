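"""Per-class carbon-stock bookkeeping mapped over the land-use grid.

Total density per class is the sum of four pools (aboveground, belowground,
soil, dead organic matter, all t/hm²); a cell's stock is density × cell area.
Because the model is purely table-driven, a tabular closed form
(Σ class area × density) is provided alongside the raster path; the two agree
to machine precision and the fast path is what the pipeline uses for totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accounting import class_areas
from .grids import HM2_PER_KM2, LandUseRaster
from .params import CarbonDensityRecord, class_lookup_grid


@dataclass
class CarbonResult:
    stock_t: np.ndarray            # per-cell stock (t)
    class_totals_1e8t: pd.Series   # per-class totals (10⁸ t)
    total_1e8t: float


def total_density(rec: CarbonDensityRecord, class_name: str) -> float:
    """Total carbon density of one class (t/hm²): sum of the four pools."""
    return rec.total_density(class_name)


def class_totals_tabular(lu: LandUseRaster, rec: CarbonDensityRecord) -> pd.Series:
    """Closed-form per-class totals (10⁸ t): area(hm²) × total density."""
    areas_hm2 = class_areas(lu) * HM2_PER_KM2
    dens = pd.Series({c: rec.total_density(c) for c in areas_hm2.index})
    return (areas_hm2 * dens) / 1e8


def carbon_stock(lu: LandUseRaster, rec: CarbonDensityRecord) -> CarbonResult:
    """Per-cell carbon stock raster plus class and domain totals."""
    if lu.cell_size_km <= 0:
        raise ValueError("cell size must be positive")
    density = class_lookup_grid(
        lu.codes, {c: rec.total_density(c) for c in rec.pools.index})
    density[~lu.valid] = 0.0
    stock = density * lu.cell_area_km2 * HM2_PER_KM2
    totals = class_totals_tabular(lu, rec)
    return CarbonResult(stock, totals, float(totals.sum()))
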