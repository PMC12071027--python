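"""Outlier screening for the factorial results table.

Before ANOVA, gross training failures are screened out of the results table:
runs whose AUC or F1 falls below hard adequacy thresholds (defaults 0.65 and
0.45) are excluded.  Three complementary univariate statistics document each
exclusion: studentized z-scores (with and without deleting the observation
from mean/sd), MAD-based modified Z-scores (robust to the outliers
themselves), and Grubbs' test for a single extreme value in a normal sample
with its t-based p-value approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "zscores",
    "modified_zscores",
    "grubbs",
    "GrubbsResult",
    "OutlierReport",
    "screen_results",
]


def _as_vector(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    return x


def zscores(values, deletion: bool = False) -> np.ndarray:
    """Studentized values z_i = (x_i - mean)/sd with the n-1 sd.

    With ``deletion=True``, the mean and sd for each z_i exclude observation i
    itself, which prevents a gross outlier from masking itself by inflating
    the scale it is measured against.
    """
    x = _as_vector(values)
    n = x.size
    if deletion:
        if n < 3:
            raise ValueError("deletion z-scores require n >= 3")
        out = np.empty(n)
        for i in range(n):
            rest = np.delete(x, i)
            s = rest.std(ddof=1)
            if s == 0:
                raise ValueError("constant sample after deletion: sd is zero")
            out[i] = (x[i] - rest.mean()) / s
        return out
    if n < 2:
        raise ValueError("z-scores require n >= 2")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("constant sample: sd is zero")
    return (x - x.mean()) / s


def modified_zscores(values) -> np.ndarray:
    """MAD-based modified Z-scores M_i = 0.6745 (x_i - median)/MAD."""
    x = _as_vector(values)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError(
            "MAD is zero (more than half the values are identical); "
            "modified Z-scores are undefined for this sample"
        )
    return 0.6745 * (x - med) / mad


@dataclass(frozen=True)
class GrubbsResult:
    """Outcome of Grubbs' test for one extreme value.

    ``t_max`` is the largest absolute studentized value (no deletion);
    ``statistic`` is its t-scale transform with n-2 degrees of freedom;
    ``p_value`` is the two-sided approximation (upper-tail t probability
    multiplied by 2n, clipped to [0, 1]); ``index`` locates the most extreme
    observation (ties broken by lower index); ``outlier`` records whether
    p < alpha.
    """

    t_max: float
    statistic: float
    n: int
    p_value: float
    index: int
    outlier: bool
    alpha: float


def grubbs(values, alpha: float = 0.05) -> GrubbsResult:
    """Grubbs' test for a single outlier in a univariate normal sample.

    The largest absolute studentized value t_max is mapped to the t scale by

        t^2 = n (n-2) t_max^2 / ((n-1)^2 - n t_max^2),

    and the two-sided p-value approximated as 2n times the upper-tail
    probability of Student's t with n-2 degrees of freedom — the standard
    correspondence behind published Grubbs critical values.  A small p-value
    indicates that the most extreme point is an outlier.
    """
    x = _as_vector(values)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs' test requires n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z = zscores(x, deletion=False)
    absz = np.abs(z)
    index = int(np.argmax(absz))  # argmax takes the lowest index on ties
    t_max = float(absz[index])
    # t_max is bounded by (n-1)/sqrt(n); the denominator is nonnegative.
    denom = (n - 1) ** 2 - n * t_max**2
    if denom <= 0:
        t_stat = np.inf
    else:
        t_stat = float(np.sqrt(n * (n - 2) * t_max**2 / denom))
    p = float(min(1.0, 2 * n * stats.t.sf(t_stat, n - 2)))
    return GrubbsResult(
        t_max=t_max,
        statistic=t_stat,
        n=n,
        p_value=p,
        index=index,
        outlier=p < alpha,
        alpha=alpha,
    )


@dataclass
class OutlierReport:
    """Audit trail of a screening pass.

    ``rows`` has one record per (removed row, offending metric) with the
    row's value, z-score, deletion z-score, modified Z-score, whether Grubbs'
    test flagged it as the sample's extreme point, and the removal reason.
    """

    rows: pd.DataFrame
    n_before: int
    n_after: int

    @property
    def n_removed(self) -> int:
        return self.n_before - self.n_after

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)
        with open(path, "a") as fh:
            fh.write(f"# n_before={self.n_before},n_after={self.n_after}\n")


_REPORT_COLUMNS = [
    "row",
    "metric",
    "value",
    "z",
    "z_deleted",
    "modified_z",
    "grubbs_flag",
    "reason",
]


def _column_stats(x: np.ndarray):
    """Screening statistics for one metric column, degenerate-safe."""
    n = x.size
    try:
        z = zscores(x)
    except ValueError:
        z = np.full(n, np.nan)
    try:
        zd = zscores(x, deletion=True)
    except ValueError:
        zd = np.full(n, np.nan)
    try:
        mz = modified_zscores(x)
    except ValueError:
        mz = np.full(n, np.nan)
    try:
        g = grubbs(x)
    except ValueError:
        g = None
    return z, zd, mz, g


def screen_results(
    table: pd.DataFrame,
    auc_min: float = 0.65,
    f1_min: float = 0.45,
    combine: str = "or",
) -> tuple[pd.DataFrame, OutlierReport]:
    """Remove inadequate runs from a results table and report why.

    With ``combine='or'`` (default) a row is removed when AUC < auc_min OR
    F1 < f1_min — each metric's criterion suffices on its own; ``'and'``
    requires both.  The report carries, for every removed row and offending
    metric, the z-scores, modified Z-score and Grubbs flag computed on the
    full (pre-screening) column, so either reading of the screen is auditable.
    Screening an already screened table removes nothing.
    """
    for col in ("AUC", "F1"):
        if col not in table.columns:
            raise ValueError(f"results table lacks required column {col!r}")
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")

    auc = table["AUC"].to_numpy(dtype=float)
    f1 = table["F1"].to_numpy(dtype=float)
    low_auc = auc < auc_min
    low_f1 = f1 < f1_min
    drop = (low_auc | low_f1) if combine == "or" else (low_auc & low_f1)

    records = []
    if drop.any():
        col_stats = {"AUC": _column_stats(auc), "F1": _column_stats(f1)}
        thresholds = {"AUC": auc_min, "F1": f1_min}
        flags = {"AUC": low_auc, "F1": low_f1}
        for i in np.flatnonzero(drop):
            for metric in ("AUC", "F1"):
                if combine == "or" and not flags[metric][i]:
                    continue
                z, zd, mz, g = col_stats[metric]
                records.append(
                    {
                        "row": int(table.index[i]),
                        "metric": metric,
                        "value": float(table[metric].iloc[i]),
                        "z": float(z[i]),
                        "z_deleted": float(zd[i]),
                        "modified_z": float(mz[i]),
                        "grubbs_flag": bool(g is not None and g.outlier and g.index == i),
                        "reason": f"{metric}<{thresholds[metric]}",
                    }
                )
    report = OutlierReport(
        rows=pd.DataFrame(records, columns=_REPORT_COLUMNS),
        n_before=len(table),
        n_after=int(len(table) - drop.sum()),
    )
    return table.loc[~drop].copy(), report
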