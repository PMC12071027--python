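"""Main-effects linear model, Type III sums of squares, and diagnostics.

The hyperparameter-sensitivity analysis treats each factor (Wd, Ly, Dp, Nt,
Nb) as categorical, fits an additive main-effects least-squares model under
sum-to-zero (effects) coding, and measures each factor's contribution by the
Type III sum of squares: the increase in residual SS when that factor's
effects are dropped from the full model while all others are retained.  With
sum-to-zero coding this is well-defined for unbalanced data, where factor SS
components need not add up to the corrected total SS.

Bounded responses such as AUC are analyzed on the logit scale
ln(p / (1 - p)), which maps (0, 1) onto the real line, reducing skewness and
stabilizing variance near the boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "logit_transform",
    "ModelFit",
    "fit_main_effects",
    "type3_anova",
    "residual_diagnostics",
]


def logit_transform(p):
    """ln(p / (1 - p)) for p strictly inside (0, 1); scalar or array."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("logit requires values strictly between 0 and 1")
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def _sorted_levels(col: pd.Series) -> list:
    levels = pd.unique(col.dropna())
    try:
        return sorted(levels)
    except TypeError:  # mixed types: fall back to string order
        return sorted(levels, key=str)


def _effects_columns(col: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero coding: one column per non-reference level.

    Column for level l is +1 on rows at l, -1 on rows at the last (reference)
    level, 0 elsewhere; the reference level's effect is minus the sum of the
    estimated ones.
    """
    ref = levels[-1]
    cols = []
    for lvl in levels[:-1]:
        c = np.where(col == lvl, 1.0, 0.0) - np.where(col == ref, 1.0, 0.0)
        cols.append(c)
    return np.column_stack(cols)


@dataclass
class ModelFit:
    """A fitted additive main-effects model with its design bookkeeping."""

    data: pd.DataFrame
    response: str
    factors: list[str]
    levels: dict[str, list]
    X: np.ndarray
    coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    sse: float
    df_resid: int
    ss_total: float
    df_total: int
    col_slices: dict[str, slice]
    _xtx_inv: np.ndarray | None = field(default=None, repr=False)

    @property
    def mse(self) -> float:
        return self.sse / self.df_resid

    @property
    def xtx_inv(self) -> np.ndarray:
        if self._xtx_inv is None:
            self._xtx_inv = np.linalg.inv(self.X.T @ self.X)
        return self._xtx_inv

    def effect(self, factor: str, level) -> float:
        """Estimated sum-to-zero effect of one factor level."""
        levels = self.levels[factor]
        sl = self.col_slices[factor]
        betas = self.coef[sl]
        if level == levels[-1]:
            return float(-betas.sum())
        return float(betas[levels.index(level)])


def _lstsq_sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)


def fit_main_effects(
    table: pd.DataFrame, response: str, factors: list[str]
) -> ModelFit:
    """Least-squares fit of ``response`` on additive categorical factor effects.

    Sum-to-zero encoding, no interactions.  Factor levels are treated as
    categorical even when their labels are numeric.
    """
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    y = table[response].to_numpy(dtype=float)
    n = y.size
    levels: dict[str, list] = {}
    blocks = [np.ones((n, 1))]
    col_slices: dict[str, slice] = {}
    pos = 1
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"factor column {f!r} not in table")
        lv = _sorted_levels(table[f])
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
        counts = table[f].value_counts()
        empty = [l for l in lv if counts.get(l, 0) == 0]
        if empty:
            raise ValueError(f"factor {f!r} has empty level {empty[0]!r}")
        levels[f] = lv
        block = _effects_columns(table[f], lv)
        blocks.append(block)
        col_slices[f] = slice(pos, pos + block.shape[1])
        pos += block.shape[1]
    X = np.column_stack(blocks)
    if n <= X.shape[1]:
        raise ValueError("not enough observations for the model degrees of freedom")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (confounded factor levels)")
    coef, sse = _lstsq_sse(X, y)
    fitted = X @ coef
    residuals = y - fitted
    ss_total = float(np.sum((y - y.mean()) ** 2))
    return ModelFit(
        data=table.reset_index(drop=True),
        response=response,
        factors=list(factors),
        levels=levels,
        X=X,
        coef=coef,
        fitted=fitted,
        residuals=residuals,
        sse=sse,
        df_resid=n - X.shape[1],
        ss_total=ss_total,
        df_total=n - 1,
        col_slices=col_slices,
    )


def type3_anova(fit: ModelFit) -> pd.DataFrame:
    """Type III ANOVA table: per-factor SS, df, MS, F and p, plus residual/total.

    SS_factor = SSE(model with that factor's effect columns removed, all other
    factors retained) - SSE(full model), under sum-to-zero coding.
    """
    y = fit.data[fit.response].to_numpy(dtype=float)
    rows = []
    for f in fit.factors:
        sl = fit.col_slices[f]
        keep = np.ones(fit.X.shape[1], dtype=bool)
        keep[sl] = False
        _, sse_red = _lstsq_sse(fit.X[:, keep], y)
        ss = max(sse_red - fit.sse, 0.0)
        df = len(fit.levels[f]) - 1
        ms = ss / df
        if fit.mse > 0:
            fstat = ms / fit.mse
            p = float(stats.f.sf(fstat, df, fit.df_resid))
        else:  # perfect fit: any nonzero factor SS is infinitely significant
            fstat = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        rows.append(
            {"Source": f, "SumSq": ss, "Df": df, "MeanSq": ms, "F": fstat, "p": p}
        )
    rows.append(
        {
            "Source": "Residual",
            "SumSq": fit.sse,
            "Df": fit.df_resid,
            "MeanSq": fit.mse,
            "F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "Source": "Total",
            "SumSq": fit.ss_total,
            "Df": fit.df_total,
            "MeanSq": np.nan,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows, columns=["Source", "SumSq", "Df", "MeanSq", "F", "p"])


def residual_diagnostics(fit: ModelFit) -> dict:
    """Residual checks for the ANOVA assumptions.

    Returns a dict with:

    - ``predicted`` / ``residuals``: pairs for the homoscedasticity plot;
    - ``qq_theoretical`` / ``qq_ordered``: normal quantiles vs ordered
      residuals for the Q-Q plot;
    - ``shapiro``: (statistic, p) Shapiro-Wilk normality test on residuals,
      or None (with a warning) when n is too small;
    - ``levene``: (statistic, p) Brown-Forsythe (median-centered Levene) test
      of equal residual variance across the design cells, or None when there
      are not enough populated cells.
    """
    res = fit.residuals
    n = res.size
    out: dict = {"predicted": fit.fitted.copy(), "residuals": res.copy()}
    order = np.sort(res)
    # Blom plotting positions for the normal Q-Q plot
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    out["qq_theoretical"] = stats.norm.ppf(probs)
    out["qq_ordered"] = order

    if n >= 3:
        stat, p = stats.shapiro(res)
        out["shapiro"] = (float(stat), float(p))
    else:
        warnings.warn("too few residuals for the Shapiro-Wilk test; omitted")
        out["shapiro"] = None

    cells = fit.data.groupby(fit.factors, observed=True).indices
    groups = [res[idx] for idx in cells.values() if len(idx) >= 2]
    if len(groups) >= 2:
        stat, p = stats.levene(*groups, center="median")
        out["levene"] = (float(stat), float(p))
    else:
        warnings.warn("fewer than 2 replicated design cells; Levene test omitted")
        out["levene"] = None
    return out
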