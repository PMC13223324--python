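"""Land-use change accounting: class areas, transfer matrices, change rates.

Orientation convention: transfer-matrix rows are the earlier year, columns
the later year, so column sums reproduce the later year's class areas.
Cells that are nodata in either year are dropped from the matrix and from
both marginals (symmetric-mask rule), which keeps total area conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CLASS_CODES, CLASS_NAMES, LandUseRaster

_CLASS_INDEX = pd.Index([CLASS_NAMES[c] for c in CLASS_CODES], name="class")


def class_areas(lu: LandUseRaster) -> pd.Series:
    """Area (km²) per land-use class; nodata excluded, absent classes zero."""
    valid = lu.valid
    counts = np.bincount(lu.codes[valid].ravel(), minlength=max(CLASS_CODES) + 1)
    areas = pd.Series({CLASS_NAMES[c]: counts[c] * lu.cell_area_km2
                       for c in CLASS_CODES}, name=lu.year or "area_km2")
    return areas.reindex(_CLASS_INDEX)


@dataclass
class TransferMatrix:
    """Class×class area flows between two years, with marginals and change rates."""

    matrix: pd.DataFrame          # km²; rows t0, columns t1
    sum_t0: pd.Series
    sum_t1: pd.Series
    abs_change: pd.Series
    pct_change: pd.Series

    @property
    def total_area(self) -> float:
        return float(self.matrix.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        """Matrix plus labelled marginal/change rows, as printed tables lay it out."""
        out = self.matrix.copy()
        out.loc["sum_t0"] = self.sum_t0
        out.loc["sum_t1"] = self.sum_t1
        out.loc["abs_change"] = self.abs_change
        out.loc["pct_change"] = self.pct_change.round(2)
        return out


def transfer_matrix(lu0: LandUseRaster, lu1: LandUseRaster) -> TransferMatrix:
    """Area flow (km²) from each class at t0 to each class at t1."""
    if lu0.codes.shape != lu1.codes.shape:
        raise ValueError(f"grid shapes differ: {lu0.codes.shape} vs {lu1.codes.shape}")
    if lu0.cell_size_km != lu1.cell_size_km:
        raise ValueError("cell sizes differ between years")
    both = lu0.valid & lu1.valid
    c0, c1 = lu0.codes[both], lu1.codes[both]
    n = max(CLASS_CODES) + 1
    flows = np.bincount(c0 * n + c1, minlength=n * n).reshape(n, n)
    mat = pd.DataFrame(
        flows[np.ix_(CLASS_CODES, CLASS_CODES)] * lu0.cell_area_km2,
        index=_CLASS_INDEX.copy(), columns=_CLASS_INDEX.copy())
    s0, s1 = mat.sum(axis=1), mat.sum(axis=0)
    change = change_stats(s0, s1)
    return TransferMatrix(mat, s0, s1, change["abs_change"], change["pct_change"])


def change_stats(t0: pd.Series, t1: pd.Series) -> pd.DataFrame:
    """Absolute and percent change per class between two area/value tables.

    Percent change is undefined (NaN) where the earlier value is zero.
    """
    if not t0.index.equals(t1.index):
        t1 = t1.reindex(t0.index)
        if t1.isna().any():
            raise ValueError("tables do not share a codebook")
    absolute = t1 - t0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * absolute.to_numpy() / t0.to_numpy()
    pct = pd.Series(np.where(t0.to_numpy() == 0, np.nan, pct), index=t0.index)
    return pd.DataFrame({"abs_change": absolute, "pct_change": pct})
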