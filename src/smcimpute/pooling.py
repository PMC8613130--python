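"""Rubin's rules for combining estimates across imputations.

Pooled point estimate = mean of the per-imputation estimates; total
variance = within-imputation variance + (1 + 1/m) x between-imputation
variance; degrees of freedom by Rubin's 1987 formula with the
Barnard-Rubin small-sample adjustment; 95% intervals on the t scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import FitResult

__all__ = ["PooledEstimates", "rubin_pool", "coverage_hit", "pool_fits"]

logger = logging.getLogger("smcimpute")


@dataclass
class PooledEstimates:
    names: list[str]
    qbar: np.ndarray        # pooled point estimates
    ubar: np.ndarray        # within-imputation variance
    b: np.ndarray           # between-imputation variance
    t: np.ndarray           # total variance = ubar + (1 + 1/m) b
    df: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    m: int
    flagged: bool = False   # > 20% of fits dropped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.names,
            "estimate": self.qbar,
            "se": np.sqrt(self.t),
            "df": self.df,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        })


def rubin_pool(estimates: np.ndarray, variances: np.ndarray,
               df_com: float, names: list[str] | None = None,
               conf_level: float = 0.95) -> PooledEstimates:
    """Pool an (m, p) array of estimates and their sampling variances.

    ``df_com`` is the complete-data degrees of freedom entering the
    Barnard-Rubin adjustment (here: number of clusters minus number of
    fixed effects, a conservative choice for level-2-varying quantities).
    """
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    variances = np.atleast_2d(np.asarray(variances, dtype=float))
    m, p = estimates.shape
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    if variances.shape != (m, p):
        raise ValueError("estimates and variances must align")
    if names is None:
        names = [f"p{i}" for i in range(p)]

    qbar = estimates.mean(axis=0)
    b = estimates.var(axis=0, ddof=1)
    ubar = variances.mean(axis=0)
    t = ubar + (1 + 1 / m) * b

    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (1 + 1 / m) * b / ubar
        nu_old = (m - 1) * (1 + 1 / np.where(rel > 0, rel, np.nan)) ** 2
        gamma = (1 + 1 / m) * b / t
        nu_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - gamma)
        df = np.where(b > 0, 1.0 / (1.0 / nu_old + 1.0 / nu_obs), nu_obs)
    df = np.maximum(df, 1e-8)

    tcrit = stats.t.ppf(0.5 + conf_level / 2, df)
    half = tcrit * np.sqrt(t)
    return PooledEstimates(list(names), qbar, ubar, b, t, df,
                           qbar - half, qbar + half, m)


def coverage_hit(pooled: PooledEstimates, truth) -> np.ndarray:
    """True where the (closed) confidence interval contains the truth."""
    truth = np.asarray(truth, dtype=float)
    return (pooled.ci_lower <= truth) & (truth <= pooled.ci_upper)


def pool_fits(fits: list[FitResult], df_com: float | None = None
              ) -> tuple[PooledEstimates, dict[str, float]]:
    """Pool a list of per-imputation model fits.

    Non-converged fits are dropped (with a logged count); if more than 20%
    are dropped the result is flagged.  Variance components are averaged
    across imputations (point summaries only).
    """
    ok = [f for f in fits if f.converged]
    dropped = len(fits) - len(ok)
    if dropped:
        logger.warning("dropped %d/%d non-converged fits", dropped, len(fits))
    if len(ok) < 2:
        raise ValueError("fewer than 2 converged fits to pool")
    names = ok[0].coef_names
    if df_com is None:
        df_com = max(ok[0].n_clusters_used - len(names), 1)
    est = np.stack([f.beta for f in ok])
    var = np.stack([f.se ** 2 for f in ok])
    pooled = rubin_pool(est, var, df_com, names)
    pooled.flagged = dropped > 0.2 * len(fits)
    varcomps: dict[str, float] = {}
    for key in ok[0].varcomp_dict():
        varcomps[key] = float(np.mean([f.varcomp_dict()[key] for f in ok]))
    return pooled, varcomps
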