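"""Trough-to-peak SCR scoring, zero-response flooring, non-responder
classification and first-trial exclusions.

Amplitudes are scored on the downsampled 10 Hz grid: the trough is the
minimum within a stimulus-specific post-onset window (0.9-3.5 s after CS
onset, 0.9-2.5 s after US onset), the peak is the maximum within 5 s after
the trough (truncated at the next US onset if that comes first), and
amplitudes below 0.01 uS are floored to exact zero responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScoringWindows:
    """Trough-search windows (s after onset), maximal rise time and the
    minimal amplitude below which a response counts as zero."""

    cs_trough: tuple[float, float] = (0.9, 3.5)
    us_trough: tuple[float, float] = (0.9, 2.5)
    max_rise: float = 5.0
    floor: float = 0.01

    def __post_init__(self) -> None:
        for lo, hi in (self.cs_trough, self.us_trough):
            if not lo < hi:
                raise ValueError("trough window must be well-ordered")
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        if self.max_rise <= 0:
            raise ValueError("max_rise must be positive")


@dataclass(frozen=True)
class Waveform:
    """Skin-conductance samples (uS) at a fixed rate, starting at time t0."""

    samples: np.ndarray
    rate: float = 10.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + (self.samples.size - 1) / self.rate


class ScoreResult(NamedTuple):
    amplitude: float  # uS; NaN when the trial could not be scored
    reason: str | None  # reason code for missing values


def score_trough_to_peak(
    w: Waveform,
    onset: float,
    kind: str = "CS",
    windows: ScoringWindows | None = None,
    next_us_onset: float | None = None,
) -> ScoreResult:
    """Score one trial; returns (amplitude, reason).

    Trough = earliest minimum within the kind-specific window after onset;
    peak = maximum between the trough and trough + max_rise, truncated at
    ``next_us_onset`` when the US occurs earlier. Window endpoints are
    inclusive on the sample grid. Amplitudes below the floor become exact 0.
    Trials whose search windows fall outside the recording are returned as
    missing with a reason code.
    """
    windows = windows or ScoringWindows()
    if kind not in ("CS", "US"):
        raise ValueError("kind must be 'CS' or 'US'")
    lo, hi = windows.cs_trough if kind == "CS" else windows.us_trough
    t = w.times
    eps = 0.5 / w.rate  # tolerate float jitter at window endpoints
    in_win = (t >= onset + lo - eps) & (t <= onset + hi + eps)
    if onset + lo < w.t0 - eps or onset + hi > w.t_end + eps or not in_win.any():
        return ScoreResult(float("nan"), "window_outside_recording")
    idx = np.flatnonzero(in_win)
    trough_i = idx[int(np.argmin(w.samples[idx]))]  # earliest minimum
    t_trough = t[trough_i]
    rise_end = t_trough + windows.max_rise
    if next_us_onset is not None:
        rise_end = min(rise_end, next_us_onset)
    if rise_end > w.t_end + eps:
        return ScoreResult(float("nan"), "rise_window_outside_recording")
    in_rise = (t >= t_trough - eps) & (t <= rise_end + eps)
    peak = float(w.samples[in_rise].max())
    amp = peak - float(w.samples[trough_i])
    if amp < windows.floor:
        amp = 0.0
    return ScoreResult(amp, None)


def flag_nonresponders(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, timepoint, day) non-responder flags.

    Day 1: non-responder when more than two-thirds of the acquisition US
    trials (i.e. more than 9 of 14) are zero responses. Day 2: non-responder
    when none of the three reinstatement USs evoked a response. When US
    trials are missing the flag is computed on the available trials and the
    shortfall reported in ``n_missing``.
    """
    rows = []
    for (pid, tp), g in table.groupby(["participant", "timepoint"], sort=True):
        acq_us = g[(g["phase"] == "ACQ") & (g["stimulus"] == "US")]["value"].dropna()
        ri_us = g[(g["phase"] == "RI") & (g["stimulus"] == "US")]["value"].dropna()
        n1, n2 = len(acq_us), len(ri_us)
        flag1 = n1 > 0 and (acq_us == 0).sum() > (2.0 / 3.0) * n1
        flag2 = n2 > 0 and bool((ri_us == 0).all())
        rows.append({"participant": pid, "timepoint": tp, "day": 1,
                     "nonresponder": bool(flag1), "n_us_trials": n1,
                     "n_missing": max(0, 14 - n1)})
        rows.append({"participant": pid, "timepoint": tp, "day": 2,
                     "nonresponder": bool(flag2), "n_us_trials": n2,
                     "n_missing": max(0, 3 - n2)})
    return pd.DataFrame(rows)


def drop_nonresponders(table: pd.DataFrame, flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Remove participants flagged as non-responders on either day of a
    timepoint (the default pipeline behaviour; flagging alone is an
    annotation)."""
    if flags is None:
        flags = flag_nonresponders(table)
    bad = flags[flags["nonresponder"]][["participant", "timepoint"]].drop_duplicates()
    if bad.empty:
        return table.copy()
    merged = table.merge(bad.assign(_drop=True), on=["participant", "timepoint"], how="left")
    return merged[merged["_drop"].isna()].drop(columns="_drop").reset_index(drop=True)


def apply_trial_exclusions(table: pd.DataFrame) -> pd.DataFrame:
    """Label trial roles and drop pre-learning trials.

    No learning can have occurred at the first CS presentations of
    acquisition, so the first CS+ and the first CS- acquisition trials are
    dropped. The first extinction CS+ and CS- trials are a 24-h delayed test
    of fear recall: they are relabelled ``role='fear_recall'`` and thereby
    removed from the extinction pool. All US trials are retained. Idempotent:
    decisions key on the original trial index, never on renumbered positions.
    """
    out = table.copy()
    if "role" not in out.columns:
        out["role"] = "retained"
    is_cs = out["stimulus"].isin(["CSP", "CSM"])
    for phase in ("ACQ", "EXT"):
        if not (out["phase"] == phase).any():
            warnings.warn(f"phase {phase} absent; exclusions are a no-op for it", stacklevel=2)
    drop = (out["phase"] == "ACQ") & is_cs & (out["trial"] == 1)
    out = out[~drop]
    recall = (out["phase"] == "EXT") & out["stimulus"].isin(["CSP", "CSM"]) & (out["trial"] == 1)
    out.loc[recall, "role"] = "fear_recall"
    return out.reset_index(drop=True)
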