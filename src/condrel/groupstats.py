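"""Longitudinal reliability at the group level.

Group-average responses per trial at T0 are regressed on those at T1 by
ordinary least squares; the explained variance R^2 (which equals the squared
Pearson correlation of the two trial-mean vectors) with its F(1, n-2) test is
the group-level reliability index for trial-based measures. For statistic
maps, the group-level index is the Jaccard/Dice overlap of the thresholded
group maps at the two timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .maps import BinaryMask, StatMap, dice, jaccard, threshold_map

__all__ = [
    "RegressionResult",
    "simple_regression",
    "group_trial_regression",
    "f_from_r_squared",
    "p_from_f",
    "OverlapResult",
    "group_overlap",
]


@dataclass
class RegressionResult:
    """Simple linear regression summary. In simple regression beta_std equals
    the Pearson correlation of x and y, and f_stat = (R^2/(1-R^2)) * df2."""

    slope: float
    intercept: float
    beta_std: float
    se: float
    t: float
    p: float
    r_squared: float
    f_stat: float
    df1: int
    df2: int
    n: int
    se_type: str = "classical"


def f_from_r_squared(r_squared: float, df2: int) -> float:
    """F statistic of a simple regression implied by its R^2: (R^2/(1-R^2))*df2."""
    if not 0.0 <= r_squared < 1.0:
        raise ValueError("r_squared must be in [0, 1)")
    return r_squared / (1.0 - r_squared) * df2


def p_from_f(f_stat: float, df1: int, df2: int) -> float:
    return float(stats.f.sf(f_stat, df1, df2))


def simple_regression(x, y) -> RegressionResult:
    """OLS of y on x with classical standard errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("simple regression requires at least 3 points")
    if np.std(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    df2 = n - 2
    f_stat = f_from_r_squared(r2, df2) if r2 < 1.0 else np.inf
    sy = y.std(ddof=1)
    beta = res.slope * x.std(ddof=1) / sy if sy > 0 else np.nan
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept), beta_std=float(beta),
        se=float(res.stderr), t=float(t), p=float(res.pvalue), r_squared=float(r2),
        f_stat=float(f_stat), df1=1, df2=df2, n=n,
    )


def _trial_means(table: pd.DataFrame, phase: str, stimulus: str) -> pd.DataFrame:
    """Trial-wise group means per timepoint (available-case over participants)."""
    sub = table[table["phase"] == phase]
    if "role" in sub.columns:
        sub = sub[sub["role"] == "retained"]
    if stimulus == "DISC":
        from .transforms import cs_discrimination

        sub = cs_discrimination(sub)
        sub = sub[sub["stimulus"] == "DISC"]
    else:
        sub = sub[sub["stimulus"] == stimulus]
    return (sub.dropna(subset=["value"])
            .groupby(["timepoint", "trial"])["value"].mean().unstack("timepoint"))


def group_trial_regression(table: pd.DataFrame, phase: str, stimulus: str) -> RegressionResult:
    """Regress T1 trial-wise group means on T0 trial-wise group means.

    Retained trials only (13 CS trials after first-trial exclusion; all 14 US
    trials), group-averaged over participants with a valid value on that
    trial. Phases with fewer than 3 trials are rejected: a correlation of two
    data points is not meaningful.
    """
    wide = _trial_means(table, phase, stimulus).dropna()
    if wide.shape[0] < 3:
        raise ValueError(f"group regression needs >= 3 trials, got {wide.shape[0]}")
    return simple_regression(wide["T0"].to_numpy(), wide["T1"].to_numpy())


@dataclass
class OverlapResult:
    jaccard: float
    dice: float
    n_voxels_t0: int
    n_voxels_t1: int
    both_empty: bool


def group_overlap(map_t0: StatMap, map_t1: StatMap, p: float = 0.01,
                  region: BinaryMask | None = None) -> OverlapResult:
    """Jaccard/Dice overlap of the two thresholded group-level t-maps."""
    m0 = threshold_map(map_t0, p)
    m1 = threshold_map(map_t1, p)
    if region is not None:
        m0 = BinaryMask(m0.data & region.data, m0.voxel_size, m0.affine)
        m1 = BinaryMask(m1.data & region.data, m1.voxel_size, m1.affine)
    return OverlapResult(
        jaccard=jaccard(m0, m1), dice=dice(m0, m1),
        n_voxels_t0=m0.n_voxels, n_voxels_t1=m1.n_voxels,
        both_empty=(m0.n_voxels == 0 and m1.n_voxels == 0),
    )
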