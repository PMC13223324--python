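"""Cross-sectional trade-off/synergy analysis among services.

Pearson correlations are computed per year across regions (cities/counties):
a positive coefficient marks a synergy, a negative one a trade-off.
Significance stars follow the usual convention (* p<0.05, ** p<0.01,
*** p<0.001, ns otherwise) from the two-sided t test with n−2 degrees of
freedom.  Temporal correlation is deliberately not offered — with four time
points it would be meaningless.  Raw p-values are reported by default; a
Benjamini–Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .summary import PER_UNIT_COLUMNS, SERVICE_COLUMNS


def _stars(p: float) -> str:
    if np.isnan(p):
        return "undef"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pearson(x, y) -> tuple[float, float, str]:
    """Pearson r with two-sided p and star label.

    Zero variance in either variable yields (nan, nan, 'undef').
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), "undef"
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), _stars(p)


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int


def _corr_matrix(df: pd.DataFrame, bh_adjust: bool = False) -> CorrelationMatrix:
    cols = list(df.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    raw = []
    for i in range(k):
        for j in range(i + 1, k):
            ri, pi, _ = pearson(df[cols[i]], df[cols[j]])
            r.iloc[i, j] = r.iloc[j, i] = ri
            p.iloc[i, j] = p.iloc[j, i] = pi
            raw.append((i, j, pi))
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests
        pvals = [t[2] for t in raw]
        ok = ~np.isnan(pvals)
        adj = np.full(len(pvals), np.nan)
        if ok.any():
            adj[ok] = multipletests(np.asarray(pvals)[ok], method="fdr_bh")[1]
        for (i, j, _), a in zip(raw, adj):
            p.iloc[i, j] = p.iloc[j, i] = a
    stars = p.map(_stars)
    for c in cols:
        stars.loc[c, c] = ""
    return CorrelationMatrix(r, p, stars, n=len(df))


def service_correlation_matrix(panel: pd.DataFrame, year: str,
                               per_unit: bool = False,
                               bh_adjust: bool = False) -> CorrelationMatrix:
    """Pairwise service correlations across regions for one year."""
    years = panel.index.get_level_values("year")
    if year not in set(years):
        raise ValueError(f"year {year!r} not in panel")
    sub = panel.xs(year, level="year")
    if len(sub) < 3:
        raise ValueError("need at least 3 regions")
    cols = list(PER_UNIT_COLUMNS if per_unit else SERVICE_COLUMNS)
    return _corr_matrix(sub[cols], bh_adjust=bh_adjust)


def proportion_correlations(panel: pd.DataFrame, proportions: pd.DataFrame,
                            year: str, per_unit: bool = True,
                            columns: list[str] | None = None) -> pd.DataFrame:
    """Tidy service × land-use-proportion correlation table.

    One row per (service, class) with columns r, p and the star label.
    ``columns`` overrides the default service-column selection.
    """
    years = panel.index.get_level_values("year")
    if year not in set(years):
        raise ValueError(f"year {year!r} not in panel")
    sv = panel.xs(year, level="year")
    pr = proportions.xs(year, level="year").reindex(sv.index)
    cols = columns if columns is not None else list(
        PER_UNIT_COLUMNS if per_unit else SERVICE_COLUMNS)
    rows = []
    for service in cols:
        for cls in pr.columns:
            r, p, s = pearson(sv[service], pr[cls])
            rows.append({"service": service, "class": cls, "r": r, "p": p,
                         "stars": s})
    return pd.DataFrame(rows)
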