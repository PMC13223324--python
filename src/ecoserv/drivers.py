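"""Driver attribution: how much of each service's spatial variation land use explains.

Two complementary views:

* **Hierarchical partitioning** decomposes the full-model R² over the k
  class-proportion predictors.  Predictor j's independent contribution I_j is
  its average R² increment over all entry orders — computed here with the
  closed-form subset weighting |S|!(k−|S|−1)!/k! over all 2^k subset fits —
  and its joint contribution is J_j = R²({j}) − I_j.  Σ I_j equals the
  full-model R² identically (Shapley efficiency), and negative I_j under
  suppression are reported, not clipped.

* **Stepwise regression** (SPSS-style bidirectional p-value selection,
  α_in = 0.05, α_out = 0.10) yields a sparse per-service equation whose
  coefficients and R² are recomputed from the final OLS fit.

The proportion predictors sum to one across classes, so the full design is
rank-deficient with an intercept; R² is computed from the least-norm fit,
which leaves fitted values (hence R²) unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm


def ols_r2(y, x) -> float:
    """Coefficient of determination of a least-squares fit with intercept.

    Rank-deficient designs fall back to the minimum-norm solution; fitted
    values are unique so R² stays well-defined.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.shape[0]:
        x = x.T
    if y.shape[0] < x.shape[1] + 2:
        raise ValueError("need at least p + 2 observations")
    design = np.column_stack([np.ones(y.shape[0]), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / tss


@dataclass
class HpResult:
    independent: pd.Series     # I_j
    joint: pd.Series           # J_j = R²({j}) − I_j
    percent: pd.Series         # 100·I_j / Σ I
    full_r2: float


def hierarchical_partition(y, x: pd.DataFrame, max_k: int = 12) -> HpResult:
    """Independent/joint R² contributions of each predictor.

    Enumerates all 2^k − 1 predictor subsets (k capped at ``max_k``); I_j is
    the Shapley value of predictor j with R² as the characteristic function.
    """
    x = pd.DataFrame(x)
    k = x.shape[1]
    if k > max_k:
        raise ValueError(
            f"{k} predictors would need {2**k} subset fits; reduce predictors "
            f"or raise max_k (≤ ~12 is tractable)")
    y = np.asarray(y, dtype=float)
    cols = list(x.columns)
    xv = x.to_numpy(dtype=float)
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, k + 1):
        for subset in combinations(range(k), size):
            r2[frozenset(subset)] = ols_r2(y, xv[:, list(subset)])
    indep = {}
    for j in range(k):
        others = [i for i in range(k) if i != j]
        total = 0.0
        for size in range(k):
            w = factorial(size) * factorial(k - size - 1) / factorial(k)
            for subset in combinations(others, size):
                s = frozenset(subset)
                total += w * (r2[s | {j}] - r2[s])
        indep[cols[j]] = total
    independent = pd.Series(indep)
    joint = pd.Series({cols[j]: r2[frozenset({j})] for j in range(k)}) - independent
    total_i = independent.sum()
    percent = 100.0 * independent / total_i if total_i != 0 else independent * np.nan
    return HpResult(independent, joint, percent, full_r2=r2[frozenset(range(k))])


def hp_order_averaging_oracle(y, x: pd.DataFrame) -> pd.Series:
    """Brute-force I_j: average R² increment over every predictor-entry order.

    Exponential in k; intended as an independent cross-check for small k.
    """
    x = pd.DataFrame(x)
    k = x.shape[1]
    xv = x.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    sums = np.zeros(k)
    orders = list(permutations(range(k)))
    for order in orders:
        entered: list[int] = []
        prev = 0.0
        for j in order:
            entered.append(j)
            cur = ols_r2(y, xv[:, entered])
            sums[j] += cur - prev
            prev = cur
    return pd.Series(sums / len(orders), index=list(x.columns))


@dataclass
class RegressionResult:
    predictors: list[str]
    coefficients: pd.Series    # includes 'intercept'
    r2: float
    p_overall: float
    trace: list[str] = field(default_factory=list)

    def equation(self, target: str = "y") -> str:
        terms = [f"{self.coefficients['intercept']:.4f}"]
        for name in self.predictors:
            c = self.coefficients[name]
            terms.append(f"{'+' if c >= 0 else '-'} {abs(c):.4f} {name}")
        return f"{target} = " + " ".join(terms)


def stepwise(y, x: pd.DataFrame, alpha_in: float = 0.05,
             alpha_out: float = 0.10, max_cycles: int = 100) -> RegressionResult:
    """Bidirectional p-value stepwise selection.

    Repeatedly adds the excluded predictor with the smallest partial p-value
    below ``alpha_in`` (ties broken by fixed column order), then drops any
    included predictor whose p-value exceeds ``alpha_out``, until stable.
    Candidates that would make the design rank-deficient (e.g. duplicated
    columns) are skipped, so exactly one of a collinear pair can enter.
    """
    if alpha_in > alpha_out:
        raise ValueError("alpha_in must not exceed alpha_out")
    x = pd.DataFrame(x)
    y = np.asarray(y, dtype=float)
    included: list[str] = []
    trace: list[str] = []
    for _ in range(max_cycles):
        changed = False
        # forward step; skipped once the fit is numerically perfect, where
        # residual p-values are pure floating-point noise
        if included and ols_r2(y, x[included].to_numpy()) >= 1.0 - 1e-10:
            break
        best_p, best_col = alpha_in, None
        for col in x.columns:
            if col in included:
                continue
            design = sm.add_constant(x[included + [col]].to_numpy())
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            fit = sm.OLS(y, design).fit()
            p = fit.pvalues[-1]
            if np.isfinite(p) and p < best_p:
                best_p, best_col = p, col
        if best_col is not None:
            included.append(best_col)
            trace.append(f"add {best_col} (p={best_p:.3g})")
            changed = True
        # backward step
        while included:
            fit = sm.OLS(y, sm.add_constant(x[included].to_numpy())).fit()
            pvals = pd.Series(fit.pvalues[1:], index=included)
            worst = pvals.idxmax()
            if pvals[worst] > alpha_out:
                included.remove(worst)
                trace.append(f"drop {worst} (p={pvals[worst]:.3g})")
                changed = True
            else:
                break
        if not changed:
            break
    else:
        raise RuntimeError("stepwise selection did not converge in "
                           f"{max_cycles} cycles")
    fit = sm.OLS(y, sm.add_constant(x[included].to_numpy()) if included
                 else np.ones((y.shape[0], 1))).fit()
    coefs = pd.Series(fit.params,
                      index=["intercept"] + included)
    p_overall = float(fit.f_pvalue) if included else float("nan")
    return RegressionResult(included, coefs, float(fit.rsquared), p_overall, trace)


def driver_table(panel: pd.DataFrame, proportions: pd.DataFrame,
                 services: list[str], years: list[str],
                 pooled: bool = False, alpha_in: float = 0.05,
                 alpha_out: float = 0.10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average HP contributions plus per-year stepwise equations.

    HP runs per service per year (or pooled across years) on the chosen
    service columns; %I is averaged over years.  Returns
    (contribution table: class × service, equation table: tidy rows).
    """
    year_values = set(panel.index.get_level_values("year"))
    missing_years = set(years) - year_values
    if missing_years:
        raise ValueError(f"years missing from panel: {sorted(missing_years)}")
    missing_cols = set(services) - set(panel.columns)
    if missing_cols:
        raise ValueError(f"service columns missing: {sorted(missing_cols)}")
    contrib = {}
    equations = []
    for service in services:
        if pooled:
            sub = panel.loc[(slice(None), years), service]
            props = proportions.loc[sub.index]
            contrib[service] = hierarchical_partition(sub.to_numpy(), props).percent
        else:
            shares = []
            for yr in years:
                sv = panel.xs(yr, level="year")[service]
                pr = proportions.xs(yr, level="year").reindex(sv.index)
                shares.append(hierarchical_partition(sv.to_numpy(), pr).percent)
            contrib[service] = pd.concat(shares, axis=1).mean(axis=1)
        for yr in years:
            sv = panel.xs(yr, level="year")[service]
            pr = proportions.xs(yr, level="year").reindex(sv.index)
            res = stepwise(sv.to_numpy(), pr, alpha_in, alpha_out)
            equations.append({"service": service, "year": yr,
                              "equation": res.equation(service),
                              "r2": res.r2, "p": res.p_overall,
                              "n_predictors": len(res.predictors)})
    return pd.DataFrame(contrib), pd.DataFrame(equations)
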