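"""Longitudinal reliability at the individual level.

Two-way single-measure intraclass correlations computed from the ANOVA
decomposition (Shrout-Fleiss convention): consistency ICC(3,1), which
tolerates a systematic session shift, and absolute-agreement ICC(2,1),
which does not. 95% confidence intervals use the standard F-based formulas
(McGraw & Wong). Internal consistency is the odd-even split-half Pearson
correlation of averaged trials, deliberately without the Spearman-Brown
prophecy correction. Within- vs between-subject similarity compares the
Fisher-z correlation of a participant's trial (or voxel) vector with their
own vector at the later timepoint against the average z-correlation with
everyone else's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCResult",
    "icc",
    "icc_from_measures",
    "icc_accumulation",
    "InternalConsistency",
    "internal_consistency_odd_even",
    "SimilarityResult",
    "within_between_similarity",
    "ComparisonResult",
    "compare_similarity",
    "fisher_ci",
]


@dataclass
class ICCResult:
    """A single-measure ICC estimate with its ANOVA mean squares and 95% CI."""

    icc_type: str  # 'abs' (absolute agreement) or 'con' (consistency)
    estimate: float
    ci_low: float
    ci_high: float
    msr: float  # between-subject (rows) mean square
    msc: float  # between-session (columns) mean square
    mse: float  # residual mean square
    n: int  # subjects
    k: int = 2  # sessions


def _anova_ms(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    ssr = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ssc = n * ((x.mean(axis=0) - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = max(sst - ssr - ssc, 0.0)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc(measures, icc_type: str = "abs", alpha: float = 0.05) -> ICCResult:
    """ICC of a subjects x sessions matrix (listwise-complete pairs only).

    ``measures`` is an (n, k) array, a wide DataFrame, or a long DataFrame
    with columns (participant, timepoint, value). Negative estimates are
    reported as computed, never truncated at zero.
    """
    x = _as_matrix(measures)
    x = x[np.isfinite(x).all(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 complete subjects")
    if icc_type not in ("abs", "con"):
        raise ValueError("icc_type must be 'abs' or 'con'")
    msr, msc, mse = _anova_ms(x)
    if msr == 0.0 and mse == 0.0:
        raise ValueError("degenerate data: no between-subject and no residual variance")

    if icc_type == "con":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:
            lo = hi = 1.0
        else:
            f_obs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        est = (msr - mse) / denom
        # McGraw & Wong F-based interval for ICC(A,1)
        a = k * est / (n * (1 - est)) if est < 1.0 else np.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1.0 else np.inf
        if not np.isfinite(a):
            lo = hi = 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else 1.0
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    est = min(float(est), 1.0)
    lo, hi = float(min(lo, est)), float(max(hi, est))
    return ICCResult(icc_type, est, lo, min(hi, 1.0), msr, msc, mse, n, k)


def _as_matrix(measures) -> np.ndarray:
    if isinstance(measures, pd.DataFrame):
        if {"participant", "timepoint", "value"}.issubset(measures.columns):
            wide = measures.pivot_table(index="participant", columns="timepoint",
                                        values="value", aggfunc="first")
            return wide.to_numpy(dtype=float)
        return measures.to_numpy(dtype=float)
    x = np.asarray(measures, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("measures must be a subjects x sessions matrix")
    return x


def icc_from_measures(measures: pd.DataFrame, code: str, stimulus: str,
                      icc_type: str = "abs") -> ICCResult:
    """ICC across T0/T1 for one phase operationalization and stimulus."""
    sub = measures[(measures["code"] == code) & (measures["stimulus"] == stimulus)]
    return icc(sub[["participant", "timepoint", "value"]], icc_type=icc_type)


def icc_accumulation(table: pd.DataFrame, phase: str, stimulus: str,
                     icc_type: str = "abs") -> list[ICCResult]:
    """ICC curve under stepwise trial accumulation.

    For m = 1..M retained trials of the phase (chronological order, after
    exclusions), the first m trials are averaged per participant and
    timepoint and the ICC recomputed; the curve has length M.
    """
    if stimulus == "DISC":
        from .transforms import cs_discrimination

        sub = cs_discrimination(table[table["phase"] == phase])
        sub = sub[sub.get("role", "retained") == "retained"] if "role" in sub.columns else sub
    else:
        sub = table[(table["phase"] == phase) & (table["stimulus"] == stimulus)]
        if "role" in sub.columns:
            sub = sub[sub["role"] == "retained"]
    if sub.empty:
        raise ValueError(f"no retained trials for phase={phase}, stimulus={stimulus}")
    sub = sub.sort_values("trial")
    m_max = int(sub.groupby(["participant", "timepoint"])["trial"].count().max())
    curve = []
    # position of each trial within the retained, chronologically ordered set
    sub = sub.copy()
    sub["pos"] = sub.groupby(["participant", "timepoint"]).cumcount() + 1
    for m in range(1, m_max + 1):
        acc = (sub[sub["pos"] <= m]
               .groupby(["participant", "timepoint"])["value"].mean().reset_index())
        curve.append(icc(acc.rename(columns={0: "value"}), icc_type=icc_type))
    return curve


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("Fisher CI requires n >= 4")
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


@dataclass
class InternalConsistency:
    r: float
    ci_low: float
    ci_high: float
    n: int
    n_trials_odd: int
    n_trials_even: int


def internal_consistency_odd_even(table: pd.DataFrame, phase: str, stimulus: str,
                                  timepoint: str) -> InternalConsistency:
    """Odd-even split-half correlation within one timepoint and phase.

    Retained trials (chronological order; position 1 = odd) are split into
    odd and even positions, averaged per participant, and the two means
    correlated across participants. No Spearman-Brown correction is applied.
    """
    if stimulus == "DISC":
        from .transforms import cs_discrimination

        sub = cs_discrimination(table[(table["phase"] == phase)
                                      & (table["timepoint"] == timepoint)])
    else:
        sub = table[(table["phase"] == phase) & (table["stimulus"] == stimulus)
                    & (table["timepoint"] == timepoint)]
    if "role" in sub.columns:
        sub = sub[sub["role"] == "retained"]
    sub = sub.sort_values("trial").copy()
    sub["pos"] = sub.groupby("participant").cumcount()  # 0-based; even pos = odd trial
    odd = sub[sub["pos"] % 2 == 0].groupby("participant")["value"].mean()
    even = sub[sub["pos"] % 2 == 1].groupby("participant")["value"].mean()
    pair = pd.concat([odd.rename("odd"), even.rename("even")], axis=1).dropna()
    if len(pair) < 3:
        raise ValueError("internal consistency requires at least 3 participants")
    if pair["odd"].std() == 0 or pair["even"].std() == 0:
        raise ValueError("undefined correlation: zero variance in a split half")
    r = float(stats.pearsonr(pair["odd"], pair["even"])[0])
    if len(pair) >= 4:
        lo, hi = fisher_ci(r, len(pair))
    else:
        lo, hi = np.nan, np.nan  # Fisher CI needs n - 3 > 0
    counts = sub.groupby("participant")["pos"].count()
    n_odd = int(np.ceil(counts.max() / 2))
    return InternalConsistency(r, lo, hi, len(pair), n_odd, int(counts.max() - n_odd))


@dataclass
class SimilarityResult:
    """Per-participant within- and between-subject Fisher-z similarities."""

    participants: list
    within_z: np.ndarray
    between_z: np.ndarray
    excluded: list = field(default_factory=list)  # (participant, reason)
    n_between_per_participant: int = 0


def within_between_similarity(t0, t1, participants=None) -> SimilarityResult:
    """Within- vs between-subject similarity of trial or voxel vectors.

    ``t0`` and ``t1`` are (n, m) arrays of per-participant vectors aligned by
    row. within_z(i) = atanh(cor(t0[i], t1[i])); between_z(i) is the mean of
    atanh(cor(t0[i], t1[j])) over the n-1 other included participants.
    Participants with an all-zero (or constant) vector at either timepoint,
    or with |within r| = 1, are excluded: such vectors cannot be correlated
    and r = 1 maps to an infinite Fisher z.
    """
    a = np.asarray(t0, dtype=float)
    b = np.asarray(t1, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("t0 and t1 must be (n, m) arrays of equal shape")
    n = a.shape[0]
    ids = list(participants) if participants is not None else list(range(n))

    excluded: list[tuple] = []
    keep = []
    for i in range(n):
        if not (np.any(a[i] != 0) and np.any(b[i] != 0)):
            excluded.append((ids[i], "all_zero_vector"))
        elif np.std(a[i]) == 0 or np.std(b[i]) == 0:
            excluded.append((ids[i], "zero_variance"))
        else:
            keep.append(i)
    if len(keep) >= 3:
        za = _standardize_rows(a[keep])
        zb = _standardize_rows(b[keep])
        c = np.clip(za @ zb.T / a.shape[1], -1.0, 1.0)
        diag = np.diag(c)
        perfect = np.abs(diag) >= 1.0 - 1e-12
        for j, i in enumerate(keep):
            if perfect[j]:
                excluded.append((ids[i], "perfect_correlation"))
        sel = ~perfect
        keep = [i for i, s in zip(keep, sel) if s]
        c = c[np.ix_(sel, sel)]
    if len(keep) < 3:
        raise ValueError("fewer than 3 participants with valid vectors survive exclusion")
    z = np.arctanh(np.diag(c))
    zmat = np.arctanh(np.clip(c, -1 + 1e-15, 1 - 1e-15))
    m = len(keep)
    off = zmat[~np.eye(m, dtype=bool)].reshape(m, m - 1)
    return SimilarityResult(
        participants=[ids[i] for i in keep],
        within_z=z,
        between_z=off.mean(axis=1),
        excluded=excluded,
        n_between_per_participant=m - 1,
    )


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


@dataclass
class ComparisonResult:
    statistic: float
    df: float
    p: float
    cohens_d: float
    method: str  # 'paired_t' or 'welch'
    n: int


def compare_similarity(within_z, between_z, levene_alpha: float = 0.05) -> ComparisonResult:
    """Compare within- and between-subject Fisher-z similarities.

    Paired t-test by default; a Welch two-sample test on the z values when
    Levene's test rejects equality of variances at ``levene_alpha`` (the
    within-subject similarities are unaveraged and typically far more
    variable than the averaged between-subject similarities). Cohen's d is
    the mean difference over the SD of the differences.
    """
    w = np.asarray(within_z, dtype=float)
    b = np.asarray(between_z, dtype=float)
    if w.shape != b.shape or w.ndim != 1:
        raise ValueError("within_z and between_z must be 1D arrays of equal length")
    n = w.size
    if n < 3:
        raise ValueError("comparison requires at least 3 paired values")
    diffs = w - b
    if np.all(diffs == 0):
        return ComparisonResult(0.0, float(n - 1), 1.0, 0.0, "paired_t", n)
    sd_diff = diffs.std(ddof=1)
    if sd_diff <= 1e-10 * max(1.0, abs(diffs.mean())):
        raise ValueError("degenerate comparison: differences have zero variance")
    d = float(diffs.mean() / sd_diff)
    if stats.levene(w, b)[1] < levene_alpha:
        t_stat, p = stats.ttest_ind(w, b, equal_var=False)
        vw, vb = w.var(ddof=1) / n, b.var(ddof=1) / n
        df = (vw + vb) ** 2 / (vw ** 2 / (n - 1) + vb ** 2 / (n - 1))
        return ComparisonResult(float(t_stat), float(df), float(p), d, "welch", n)
    t_stat, p = stats.ttest_rel(w, b)
    return ComparisonResult(float(t_stat), float(n - 1), float(p), d, "paired_t", n)
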