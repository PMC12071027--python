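"""Least-squares means, Fisher LSD contrasts, and homogeneous groups.

After a factor is found significant in the ANOVA, its levels are compared
pairwise with Fisher's Least Significant Difference procedure: each pair of
least-squares means is compared at the per-pair t threshold with the residual
degrees of freedom, with no multiplicity correction — by construction there
is an alpha-level risk per pair when the true difference is zero.  Levels are
then summarized by homogeneous-group letters: levels sharing a letter are not
significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import ModelFit

__all__ = [
    "LevelMean",
    "ContrastRow",
    "ls_means",
    "lsd_contrasts",
    "homogeneous_groups",
    "means_table",
    "contrasts_table",
]


@dataclass(frozen=True)
class LevelMean:
    """Least-squares mean of one factor level with its CI."""

    factor: str
    level: object
    mean: float
    se: float
    lower: float
    upper: float


@dataclass(frozen=True)
class ContrastRow:
    """One pairwise LSD comparison between two factor levels."""

    factor: str
    level_a: object
    level_b: object
    difference: float  # LS mean(a) - LS mean(b)
    lsd: float  # threshold |difference| must exceed at the chosen alpha
    significant: bool


def _level_contrast(fit: ModelFit, factor: str, level) -> np.ndarray:
    """Prediction contrast for a level, averaging equally over other factors.

    Under sum-to-zero coding the other factors' effects average to zero, so
    the contrast is the intercept plus this factor's coding row.
    """
    c = np.zeros(fit.X.shape[1])
    c[0] = 1.0
    sl = fit.col_slices[factor]
    levels = fit.levels[factor]
    if level == levels[-1]:
        c[sl] = -1.0
    else:
        c[sl][levels.index(level)] = 1.0
    return c


def ls_means(fit: ModelFit, factor: str, alpha: float = 0.05) -> list[LevelMean]:
    """LS mean, standard error, and (1-alpha) CI for every level of a factor.

    The LS mean is the model prediction at that level averaging with equal
    weight over all levels of the other factors; the interval uses the t
    quantile at the fit's residual degrees of freedom.
    """
    if factor not in fit.factors:
        raise ValueError(f"factor {factor!r} not in fit")
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    out = []
    for level in fit.levels[factor]:
        c = _level_contrast(fit, factor, level)
        mean = float(c @ fit.coef)
        se = float(np.sqrt(fit.mse * c @ fit.xtx_inv @ c))
        out.append(
            LevelMean(
                factor=factor,
                level=level,
                mean=mean,
                se=se,
                lower=mean - tcrit * se,
                upper=mean + tcrit * se,
            )
        )
    return out


def lsd_contrasts(
    fit: ModelFit, factor: str, alpha: float = 0.05
) -> list[ContrastRow]:
    """Fisher LSD comparison of every unordered pair of a factor's levels.

    LSD = t(1 - alpha/2, df_resid) * SE(difference); a pair is significant
    when |difference of LS means| exceeds it.  No multiplicity correction.
    """
    if factor not in fit.factors:
        raise ValueError(f"factor {factor!r} not in fit")
    levels = fit.levels[factor]
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    rows = []
    for i, a in enumerate(levels):
        ca = _level_contrast(fit, factor, a)
        for b in levels[i + 1 :]:
            cb = _level_contrast(fit, factor, b)
            d = ca - cb
            diff = float(d @ fit.coef)
            se = float(np.sqrt(fit.mse * d @ fit.xtx_inv @ d))
            lsd = float(tcrit * se)
            rows.append(
                ContrastRow(
                    factor=factor,
                    level_a=a,
                    level_b=b,
                    difference=diff,
                    lsd=lsd,
                    significant=abs(diff) > lsd,
                )
            )
    return rows


def homogeneous_groups(
    means: list[LevelMean], contrasts: list[ContrastRow]
) -> dict:
    """Assign homogeneous-group letters to factor levels.

    Levels are sorted by LS mean; each maximal run of consecutive levels with
    no significant internal pair shares one letter.  Two levels share at
    least one letter exactly when their pairwise contrast is non-significant.
    """
    order = sorted(means, key=lambda m: m.mean)
    levels = [m.level for m in order]
    sig = {}
    for c in contrasts:
        sig[frozenset((c.level_a, c.level_b))] = c.significant
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            if frozenset((a, b)) not in sig:
                raise ValueError(f"contrast set missing pair ({a!r}, {b!r})")

    def run_ok(i: int, j: int) -> bool:
        return not any(
            sig[frozenset((levels[p], levels[q]))]
            for p in range(i, j + 1)
            for q in range(p + 1, j + 1)
        )

    runs: list[tuple[int, int]] = []
    for i in range(len(levels)):
        j = i
        while j + 1 < len(levels) and run_ok(i, j + 1):
            j += 1
        if not runs or not (runs[-1][0] <= i and j <= runs[-1][1]):
            runs.append((i, j))

    letters = {lvl: "" for lvl in levels}
    for k, (i, j) in enumerate(runs):
        letter = chr(ord("a") + k)
        for idx in range(i, j + 1):
            letters[levels[idx]] += letter
    return letters


def means_table(means: list[LevelMean], letters: dict | None = None) -> pd.DataFrame:
    """Plot-ready per-level summary (level, mean, SE, limits, letters)."""
    rows = []
    for m in means:
        rows.append(
            {
                "factor": m.factor,
                "level": m.level,
                "mean": m.mean,
                "se": m.se,
                "lower": m.lower,
                "upper": m.upper,
                "letters": letters.get(m.level, "") if letters else "",
            }
        )
    return pd.DataFrame(rows)


def contrasts_table(contrasts: list[ContrastRow]) -> pd.DataFrame:
    rows = [
        {
            "factor": c.factor,
            "level_a": c.level_a,
            "level_b": c.level_b,
            "difference": c.difference,
            "lsd": c.lsd,
            "significant": c.significant,
        }
        for c in contrasts
    ]
    return pd.DataFrame(rows)
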