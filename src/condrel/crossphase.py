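"""Cross-phase predictability of conditioned responding.

Responding in an earlier experimental phase (e.g. average acquisition) is
used to predict responding in a later phase (e.g. the first extinction
trial, a delayed test of fear recall) by simple linear regression with
HC3 heteroskedasticity-consistent standard errors. In simple regression the
standardized beta equals the Pearson correlation of predictor and criterion.
The full specification grid crosses stimulus (CS+, CS-, CS discrimination),
transformation ladder, ordinal ranking and the phase-operationalization
pairs; pooled contrasts compare Fisher-z transformed betas between groups of
grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .groupstats import RegressionResult
from .maps import BinaryMask, StatMap, pattern_correlation
from .reliability import ComparisonResult

__all__ = [
    "PredictionSpec",
    "ols_hc3",
    "strength_label",
    "default_prediction_pairs",
    "default_rating_prediction_pairs",
    "predict_grid",
    "phase_pattern_prediction",
    "pooled_beta_comparison",
]

#: Paradigm stage of each phase operationalization; a predictor must come
#: from an earlier stage than its criterion.
PHASE_STAGE = {
    "AVE_ACQ": 1, "LAST2_ACQ": 1, "POSTPRE_ACQ": 1, "POST_ACQ": 1,
    "FIRST_EXT": 2, "PRE_EXT": 2,
    "AVE_EXT": 3, "LAST2_EXT": 3, "PREPOST_EXT": 3, "POST_EXT": 3,
    "AVE_RI": 4, "FIRST_RITEST": 4, "FIRST_RITEST_RATING": 4,
}


@dataclass(frozen=True)
class PredictionSpec:
    """One grid cell: predictor/criterion operationalizations plus the data
    specification (stimulus, transform, ranked)."""

    predictor: str
    criterion: str
    stimulus: str = "DISC"
    transform: str = "RAW"
    ranked: bool = False

    def __post_init__(self) -> None:
        for code in (self.predictor, self.criterion):
            if code not in PHASE_STAGE:
                raise ValueError(f"unknown operationalization {code!r}")
        if PHASE_STAGE[self.predictor] >= PHASE_STAGE[self.criterion]:
            raise ValueError(
                f"predictor {self.predictor} must precede criterion {self.criterion}"
            )


def ols_hc3(x, y) -> RegressionResult:
    """Simple OLS with HC3 robust standard errors.

    The HC3 sandwich weights squared residuals by (1 - h_ii)^-2, where h_ii
    is the hat-matrix diagonal. beta_std = slope * sd(x)/sd(y), i.e. the
    Pearson correlation of x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("HC3 regression requires at least 3 complete pairs")
    if np.std(x) == 0:
        raise ValueError("predictor has zero variance")
    sy = y.std(ddof=1)
    if sy == 0:
        raise ValueError("criterion has zero variance; beta_std undefined")
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    h = fit.get_influence().hat_matrix_diag
    if np.any(1.0 - h < 1e-12):
        raise ValueError("leverage-degenerate design: a point has h_ii = 1")
    robust = fit.get_robustcov_results(cov_type="HC3")
    slope = float(robust.params[1])
    se = float(robust.bse[1])
    t_val = slope / se if se > 0 else (np.inf if slope > 0 else (-np.inf if slope < 0 else 0.0))
    p = float(2 * stats.t.sf(abs(t_val), n - 2)) if np.isfinite(t_val) else 0.0
    r2 = float(fit.rsquared)
    beta = slope * x.std(ddof=1) / sy
    f_stat = r2 / (1 - r2) * (n - 2) if r2 < 1.0 else np.inf
    return RegressionResult(
        slope=slope, intercept=float(robust.params[0]), beta_std=float(beta),
        se=se, t=float(t_val), p=p, r_squared=r2, f_stat=float(f_stat),
        df1=1, df2=n - 2, n=n, se_type="HC3",
    )


def strength_label(beta: float) -> str:
    """Association-strength benchmark: |beta| < 0.4 weak, >= 0.4 moderate,
    >= 0.7 strong."""
    b = abs(beta)
    if b >= 0.7:
        return "strong"
    if b >= 0.4:
        return "moderate"
    return "weak"


def default_prediction_pairs() -> list[tuple[str, str]]:
    """The 11 SCR predictor -> criterion columns of the default grid."""
    return [
        ("AVE_ACQ", "FIRST_EXT"), ("LAST2_ACQ", "FIRST_EXT"),
        ("AVE_ACQ", "AVE_EXT"), ("LAST2_ACQ", "AVE_EXT"),
        ("AVE_ACQ", "LAST2_EXT"), ("LAST2_ACQ", "LAST2_EXT"),
        ("AVE_ACQ", "FIRST_RITEST"), ("LAST2_ACQ", "FIRST_RITEST"),
        ("FIRST_EXT", "FIRST_RITEST"), ("AVE_EXT", "FIRST_RITEST"),
        ("LAST2_EXT", "FIRST_RITEST"),
    ]


def default_rating_prediction_pairs() -> list[tuple[str, str]]:
    """The 11 fear-rating predictor -> criterion columns."""
    return [
        ("POSTPRE_ACQ", "PRE_EXT"), ("POST_ACQ", "PRE_EXT"),
        ("POSTPRE_ACQ", "PREPOST_EXT"), ("POST_ACQ", "PREPOST_EXT"),
        ("POSTPRE_ACQ", "POST_EXT"), ("POST_ACQ", "POST_EXT"),
        ("POSTPRE_ACQ", "FIRST_RITEST_RATING"), ("POST_ACQ", "FIRST_RITEST_RATING"),
        ("PRE_EXT", "FIRST_RITEST_RATING"), ("PREPOST_EXT", "FIRST_RITEST_RATING"),
        ("POST_EXT", "FIRST_RITEST_RATING"),
    ]


def predict_grid(measures: pd.DataFrame, specs, timepoint: str = "T0",
                 alpha: float = 0.05) -> pd.DataFrame:
    """Run one HC3 regression per specification cell.

    ``measures`` is a long phase-measure table with columns (participant,
    timepoint, code, stimulus, transform, ranked, value); if transform/ranked
    columns are absent the measures are taken as raw/unranked. Per-cell
    failures are recorded in the ``error`` column and the grid completes.
    """
    m = measures.copy()
    if "transform" not in m.columns:
        m["transform"] = "RAW"
    if "ranked" not in m.columns:
        m["ranked"] = False
    m = m[m["timepoint"] == timepoint]
    rows = []
    for spec in specs:
        row = {"predictor": spec.predictor, "criterion": spec.criterion,
               "stimulus": spec.stimulus, "transform": spec.transform,
               "ranked": spec.ranked}
        cell = m[(m["stimulus"] == spec.stimulus) & (m["transform"] == spec.transform)
                 & (m["ranked"] == spec.ranked)]
        xs = cell[cell["code"] == spec.predictor].set_index("participant")["value"]
        ys = cell[cell["code"] == spec.criterion].set_index("participant")["value"]
        pair = pd.concat([xs.rename("x"), ys.rename("y")], axis=1).dropna()
        try:
            res = ols_hc3(pair["x"], pair["y"])
            row.update(beta_std=res.beta_std, se=res.se, t=res.t, p=res.p,
                       r_squared=res.r_squared, n=res.n,
                       significant=res.p < alpha,
                       strength=strength_label(res.beta_std), error=None)
        except ValueError as exc:
            row.update(beta_std=np.nan, se=np.nan, t=np.nan, p=np.nan,
                       r_squared=np.nan, n=len(pair), significant=False,
                       strength=None, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def phase_pattern_prediction(maps_acq, maps_ext, regions: dict[str, BinaryMask]) -> pd.DataFrame:
    """Per-region mean correlation between acquisition and extinction beta maps.

    Correlations are computed per participant, Fisher-z averaged across
    participants and transformed back. Participants with |r| = 1 are clipped
    at z = atanh(1 - 1e-12) rather than excluded.
    """
    if len(maps_acq) != len(maps_ext):
        raise ValueError("map lists must be aligned by participant")
    rows = []
    for name, region in regions.items():
        zs = []
        for a, e in zip(maps_acq, maps_ext):
            r = pattern_correlation(a, e, region)
            r = float(np.clip(r, -(1 - 1e-12), 1 - 1e-12))
            zs.append(np.arctanh(r))
        mean_r = float(np.tanh(np.mean(zs)))
        rows.append({"region": name, "mean_r": mean_r, "n": len(zs),
                     "strength": strength_label(mean_r)})
    return pd.DataFrame(rows)


def pooled_beta_comparison(grid: pd.DataFrame, column: str, group_a, group_b,
                           paired: bool | None = None,
                           levene_alpha: float = 0.05) -> ComparisonResult:
    """Compare standardized betas pooled across all other specifications.

    Betas are Fisher r-to-z transformed. When the two groups match
    cell-by-cell on every other specification column (e.g. raw vs log on the
    same predictor/criterion/stimulus/ranking), a paired t-test is used;
    otherwise a Welch test. ``paired=True`` on unmatched groups is an error.
    """
    ok = grid[grid["beta_std"].notna()]
    ga = ok[ok[column] == group_a].copy()
    gb = ok[ok[column] == group_b].copy()
    if len(ga) < 3 or len(gb) < 3:
        raise ValueError("each pooled group needs at least 3 betas")
    keys = [c for c in ("predictor", "criterion", "stimulus", "transform", "ranked")
            if c in grid.columns and c != column]
    merged = ga.merge(gb, on=keys, suffixes=("_a", "_b"))
    matched = len(merged) == len(ga) == len(gb)
    if paired is True and not matched:
        raise ValueError("paired comparison requested but cells do not match one-to-one")
    do_paired = matched if paired is None else paired

    clip = 1 - 1e-12
    if do_paired:
        za = np.arctanh(np.clip(merged["beta_std_a"].to_numpy(), -clip, clip))
        zb = np.arctanh(np.clip(merged["beta_std_b"].to_numpy(), -clip, clip))
        diffs = za - zb
        n = za.size
        if np.all(diffs == 0):
            return ComparisonResult(0.0, float(n - 1), 1.0, 0.0, "paired_t", n)
        if diffs.std(ddof=1) <= 1e-10 * max(1.0, abs(diffs.mean())):
            raise ValueError("degenerate comparison: constant non-zero difference")
        t_stat, p = stats.ttest_rel(za, zb)
        dd = float(diffs.mean() / diffs.std(ddof=1))
        return ComparisonResult(float(t_stat), float(n - 1), float(p), dd, "paired_t", n)

    za = np.arctanh(np.clip(ga["beta_std"].to_numpy(), -clip, clip))
    zb = np.arctanh(np.clip(gb["beta_std"].to_numpy(), -clip, clip))
    if stats.levene(za, zb)[1] < levene_alpha:
        t_stat, p = stats.ttest_ind(za, zb, equal_var=False)
        method = "welch"
        va, vb = za.var(ddof=1) / za.size, zb.var(ddof=1) / zb.size
        df = (va + vb) ** 2 / (va ** 2 / (za.size - 1) + vb ** 2 / (zb.size - 1))
    else:
        t_stat, p = stats.ttest_ind(za, zb, equal_var=True)
        method = "student_t"
        df = za.size + zb.size - 2
    pooled_sd = np.sqrt((za.var(ddof=1) + zb.var(ddof=1)) / 2)
    dd = float((za.mean() - zb.mean()) / pooled_sd) if pooled_sd > 0 else 0.0
    return ComparisonResult(float(t_stat), float(df), float(p), dd, method,
                            za.size + zb.size)
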