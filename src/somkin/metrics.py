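"""Model-evaluation metrics and nonparametric tests.

The agreement metrics (R², concordance correlation coefficient, RMSE, RMSEn,
AIC) are implemented from their printed definitional forms rather than any
library default, because the pipeline's model selection depends on these exact
conventions:

* R² = 1 − Σ(ŷ−y)² / Σ(y−ȳ)²  (can be negative for a bad predictor)
* ρ_c (CCC) uses raw sums of squares — no n−1 correction:
  ρ_c = 2·Σ(ŷ−ȳ_ŷ)(y−ȳ) / [ n·(ȳ_ŷ−ȳ)² + Σ(ŷ−ȳ_ŷ)² + Σ(y−ȳ)² ]
* RMSEn = RMSE / IQR(observations)
* AIC = n·ln(SSE/n) + 2p  — SSE-based, with p explanatory variables.

Lower RMSEn/AIC and higher R²/ρ_c indicate better performance.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["evaluate", "kruskal_wallis", "spearman_matrix", "quantile_summary",
           "aic_sse", "ccc"]


def _paired(y_obs, y_sim):
    y_obs = np.asarray(y_obs, dtype=float)
    y_sim = np.asarray(y_sim, dtype=float)
    if y_obs.shape != y_sim.shape or y_obs.ndim != 1:
        raise ValueError("y_obs and y_sim must be 1-D and equal length")
    if y_obs.size < 2:
        raise ValueError("need at least 2 paired observations")
    return y_obs, y_sim


def ccc(y_obs, y_sim) -> float:
    """Concordance correlation coefficient (population-sum form)."""
    y_obs, y_sim = _paired(y_obs, y_sim)
    n = y_obs.size
    do = y_obs - y_obs.mean()
    ds = y_sim - y_sim.mean()
    num = 2.0 * np.sum(ds * do)
    den = n * (y_sim.mean() - y_obs.mean()) ** 2 + np.sum(ds ** 2) + np.sum(do ** 2)
    if den == 0:
        raise ValueError("CCC undefined: both samples constant and equal means")
    return float(num / den)


def aic_sse(sse: float, n: int, p: int) -> float:
    """SSE-based Akaike Information Criterion: n·ln(SSE/n) + 2p."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    if sse < 0:
        raise ValueError("SSE must be non-negative")
    if sse == 0:
        import warnings
        warnings.warn("SSE = 0: AIC reported as -inf")
        return -np.inf
    return float(n * np.log(sse / n) + 2 * p)


def evaluate(y_obs, y_sim, p: int = 1) -> dict:
    """Full metric set {r2, ccc, rmse, rmsen, aic} for a paired sample.

    ``p`` is the number of explanatory variables entering the AIC penalty.
    RMSEn normalizes by the interquartile range of the observations and is
    undefined (error) when that IQR is zero.
    """
    y_obs, y_sim = _paired(y_obs, y_sim)
    n = y_obs.size
    res = y_sim - y_obs
    sse = float(np.sum(res ** 2))
    tss = float(np.sum((y_obs - y_obs.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else (1.0 if sse == 0 else -np.inf)
    rmse = float(np.sqrt(sse / n))
    q1, q3 = np.quantile(y_obs, [0.25, 0.75])  # linear ("type 7") interpolation
    iqr = q3 - q1
    if sse == 0:
        rmsen = 0.0
    elif iqr == 0:
        raise ValueError("RMSEn undefined: zero interquartile range of observations")
    else:
        rmsen = rmse / iqr
    return {"r2": float(r2), "ccc": ccc(y_obs, y_sim), "rmse": rmse,
            "rmsen": float(rmsen), "aic": aic_sse(sse, n, p)}


def kruskal_wallis(groups) -> dict:
    """Kruskal–Wallis rank test across ``groups`` (tie-corrected H).

    Returns ``{"H": ..., "p_value": ..., "df": ...}``; significance judged at
    0.05.  All-identical data yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p_value": 1.0, "df": len(groups) - 1}
    H, p = stats.kruskal(*groups)
    return {"H": float(H), "p_value": float(p), "df": len(groups) - 1}


def spearman_matrix(table) -> "pd.DataFrame":
    """Pairwise-complete Spearman rank-correlation matrix of a table.

    Constant columns give NaN entries (flagged by a warning), never a silent 0.
    """
    import pandas as pd

    df = pd.DataFrame(table)
    num = df.select_dtypes(include=[np.number])
    const = [c for c in num.columns if num[c].dropna().nunique() <= 1]
    if const:
        import warnings
        warnings.warn(f"constant columns yield undefined correlations: {const}")
    m = num.corr(method="spearman", min_periods=3)
    np.fill_diagonal(m.values, 1.0)
    for c in const:
        m.loc[c, :] = np.nan
        m.loc[:, c] = np.nan
        m.loc[c, c] = 1.0
    return m


def quantile_summary(values, levels=(0.5, 0.9)) -> dict:
    """Median plus symmetric central intervals of ``values``.

    The default levels give the 50% CI (25–75 percentiles) and the 90% CI
    (5–95 percentiles), using linear interpolation of order statistics.
    Returns ``{"median": m, "ci50": (lo, hi), "ci90": (lo, hi), ...}``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    out = {"median": float(np.quantile(v, 0.5))}
    for lev in levels:
        lo, hi = np.quantile(v, [(1 - lev) / 2, (1 + lev) / 2])
        out[f"ci{int(round(lev * 100))}"] = (float(lo), float(hi))
    return out
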