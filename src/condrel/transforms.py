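"""Data transformations and phase operationalizations.

The transformation ladder is RAW -> LOG -> LOG_RC: natural-log transform
ln(1 + x) (zeros stay zero), then day-wise range correction dividing each
trial by the participant's day-specific maximum over all CS and US trials
(applied to the already log-transformed values). CS discrimination is
CS+ minus CS-, trial-wise by ordinal position or on phase summaries.
Ordinal ranking converts phase measures to average ranks across participants.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

TRANSFORMS = ("RAW", "LOG", "LOG_RC")

#: SCR phase operationalizations: (phase, how) where how selects the
#: retained-trial subset that is averaged.
SCR_CODES = {
    "AVE_ACQ": ("ACQ", "mean"),
    "LAST2_ACQ": ("ACQ", "last2"),
    "FIRST_EXT": ("EXT", "fear_recall"),
    "AVE_EXT": ("EXT", "mean"),
    "LAST2_EXT": ("EXT", "last2"),
    "FIRST_RITEST": ("RITEST", "first"),
    "AVE_RI": ("RI", "mean"),  # US responses during reinstatement
}

#: Rating operationalizations: occasion, or a (post, pre) difference.
RATING_CODES = {
    "POSTPRE_ACQ": ("POST_ACQ", "PRE_ACQ"),
    "POST_ACQ": "POST_ACQ",
    "PRE_EXT": "PRE_EXT",
    "PREPOST_EXT": ("PRE_EXT", "POST_EXT"),
    "POST_EXT": "POST_EXT",
    "FIRST_RITEST_RATING": "POST_RITEST",
}

PHASE_MEASURE_COLUMNS = ["participant", "timepoint", "code", "stimulus", "value"]


def _values(obj):
    if isinstance(obj, pd.DataFrame):
        return obj["value"].to_numpy(dtype=float)
    return np.asarray(obj, dtype=float)


def log_transform(table):
    """ln(1 + x) on amplitudes; zero responses map to exactly zero.

    Accepts a tidy table (transforms the ``value`` column) or an array.
    """
    x = _values(table)
    if x.size and np.nanmin(x) < 0:
        raise ValueError("log transform requires non-negative amplitudes")
    y = np.log1p(x)
    if isinstance(table, pd.DataFrame):
        out = table.copy()
        out["value"] = y
        return out
    return y


def range_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each trial by the participant's day-specific maximum over all
    CS and US trials. Participant-days whose maximum is zero (or entirely
    missing) are flagged missing, since the ratio is undefined."""
    out = table.copy()
    day_max = out.groupby(["participant", "timepoint", "day"])["value"].transform("max")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["value"] = np.where(day_max > 0, out["value"] / day_max, np.nan)
    return out


def apply_transform(table: pd.DataFrame, transform: str) -> pd.DataFrame:
    """Apply one rung of the ladder: RAW, LOG, or LOG_RC (log then
    range correction of the log values)."""
    if transform == "RAW":
        return table.copy()
    if transform == "LOG":
        return log_transform(table)
    if transform == "LOG_RC":
        return range_correct(log_transform(table))
    raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def cs_discrimination(table: pd.DataFrame) -> pd.DataFrame:
    """Trial-level CS discrimination: k-th CS+ minus k-th CS- within each
    (participant, timepoint, phase, role), paired by within-phase ordinal
    position. Unequal trial counts are paired up to the shorter sequence
    with a warning. Returns rows with stimulus='DISC'."""
    cs = table[table["stimulus"].isin(["CSP", "CSM"])]
    keys = ["participant", "timepoint", "day", "phase"]
    if "role" in cs.columns:
        keys.append("role")
    out = []
    warned = False
    for key, g in cs.groupby(keys, sort=False):
        p = g[g["stimulus"] == "CSP"].sort_values("trial")
        m = g[g["stimulus"] == "CSM"].sort_values("trial")
        k = min(len(p), len(m))
        if len(p) != len(m) and not warned:
            warnings.warn("unequal CS+/CS- trial counts; pairing up to the shorter sequence",
                          stacklevel=2)
            warned = True
        if k == 0:
            continue
        d = p.head(k).copy()
        d["stimulus"] = "DISC"
        d["trial"] = np.arange(1, k + 1)
        d["value"] = p["value"].to_numpy()[:k] - m["value"].to_numpy()[:k]
        out.append(d)
    if not out:
        return cs.head(0).assign(stimulus=pd.Series(dtype=object))
    return pd.concat(out, ignore_index=True)


def rank_transform(values) -> np.ndarray:
    """Ascending average ranks across participants; NaN stays NaN."""
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ValueError("ranking requires at least 2 non-missing values")
    out = np.full(x.shape, np.nan)
    out[ok] = stats.rankdata(x[ok], method="average")
    return out


def rank_phase_measures(measures: pd.DataFrame) -> pd.DataFrame:
    """Rank phase-measure values across participants within each
    (timepoint, code, stimulus) cell."""
    out = measures.copy()
    out["value"] = (
        out.groupby(["timepoint", "code", "stimulus"])["value"]
        .transform(lambda s: s.rank(method="average"))
    )
    return out


def _summarize(g: pd.DataFrame, how: str) -> float:
    retained = g[g.get("role", pd.Series("retained", index=g.index)) == "retained"]
    retained = retained.sort_values("trial")
    vals = retained["value"].dropna().to_numpy()
    if how == "mean":
        return float(vals.mean()) if vals.size else np.nan
    if how == "last2":
        return float(vals[-2:].mean()) if vals.size >= 2 else np.nan
    if how == "first":
        return float(vals[0]) if vals.size else np.nan
    if how == "fear_recall":
        if "role" not in g.columns:
            return np.nan
        fr = g[g["role"] == "fear_recall"]["value"].dropna().to_numpy()
        return float(fr[0]) if fr.size else np.nan
    raise ValueError(how)


def operationalize_phase(table: pd.DataFrame, code: str,
                         ratings: pd.DataFrame | None = None) -> pd.DataFrame:
    """One value per (participant, timepoint, stimulus) for a phase code.

    SCR codes average retained trials (after first-trial exclusion), take the
    final two, the first trial, or the fear-recall trial; rating codes pick a
    rating occasion or a post-pre difference. CS discrimination rows
    (stimulus='DISC') are the CS+ summary minus the CS- summary. Participants
    with fewer trials than a code requires get a missing value.
    """
    rows = []
    if code in SCR_CODES:
        phase, how = SCR_CODES[code]
        sub = table[table["phase"] == phase]
        stimuli = ["US"] if phase == "RI" else ["CSP", "CSM"]
        for (pid, tp), g in sub.groupby(["participant", "timepoint"], sort=True):
            vals = {}
            for stim in stimuli:
                vals[stim] = _summarize(g[g["stimulus"] == stim], how)
                rows.append((pid, tp, code, stim, vals[stim]))
            if set(stimuli) == {"CSP", "CSM"}:
                rows.append((pid, tp, code, "DISC", vals["CSP"] - vals["CSM"]))
    elif code in RATING_CODES:
        if ratings is None:
            raise ValueError(f"code {code!r} requires the rating table")
        spec = RATING_CODES[code]
        for (pid, tp), g in ratings.groupby(["participant", "timepoint"], sort=True):
            vals = {}
            for stim in ("CSP", "CSM"):
                gg = g[g["stimulus"] == stim].set_index("occasion")["value"]
                if isinstance(spec, tuple):
                    post, pre = spec
                    v = gg.get(post, np.nan) - gg.get(pre, np.nan)
                else:
                    v = gg.get(spec, np.nan)
                vals[stim] = float(v)
                rows.append((pid, tp, code, stim, vals[stim]))
            rows.append((pid, tp, code, "DISC", vals["CSP"] - vals["CSM"]))
    else:
        raise ValueError(f"unknown phase operationalization {code!r}")
    return pd.DataFrame(rows, columns=PHASE_MEASURE_COLUMNS)


def phase_measures(table: pd.DataFrame, ratings: pd.DataFrame | None = None,
                   codes=None) -> pd.DataFrame:
    """Long table of phase measures for several codes at once."""
    if codes is None:
        codes = list(SCR_CODES) + (list(RATING_CODES) if ratings is not None else [])
    parts = [operationalize_phase(table, c, ratings) for c in codes]
    return pd.concat(parts, ignore_index=True)
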