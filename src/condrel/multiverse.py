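"""Specification-grid (multiverse) orchestration.

Enumerates every applicable combination of analysis, stimulus,
transformation, ranking, phase operationalization and timepoint, runs the
corresponding estimator on a cohort, and emits one tidy result row per cell
(success or structured failure, never a silent drop). Reliability estimates
are classified against the customary benchmark scales for internal
consistency and ICCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crossphase, groupstats, reliability, transforms
from .scoring import apply_trial_exclusions

__all__ = ["SpecGrid", "default_grid", "run_multiverse", "classify_benchmark"]

ANALYSES = (
    "internal_consistency",
    "icc_abs",
    "icc_con",
    "similarity",
    "group_regression",
    "cross_phase",
    "overlap_individual",
    "overlap_group",
)

RESULT_COLUMNS = [
    "analysis", "timepoint", "phase_code", "stimulus", "transform", "ranked",
    "estimate", "ci_low", "ci_high", "stat", "p", "n", "benchmark", "error",
]

#: Benchmark scales; intervals are left-closed [a, b).
_BENCHMARKS = {
    "internal_consistency": [
        (0.5, "unacceptable"), (0.6, "poor"), (0.7, "questionable"),
        (0.8, "acceptable"), (0.9, "good"), (np.inf, "excellent"),
    ],
    "icc": [(0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent")],
}


def classify_benchmark(value: float, scale: str = "icc") -> str:
    """Label a reliability estimate on the conventional benchmark scale."""
    if scale not in _BENCHMARKS:
        raise ValueError(f"unknown scale {scale!r}")
    if value > 1.0:
        raise ValueError("reliability estimates cannot exceed 1")
    for upper, label in _BENCHMARKS[scale]:
        if value < upper:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class SpecGrid:
    """Which analyses to run over which data specifications.

    Only combinations that are meaningful are enumerated by default:
    internal consistency is trial-based (SCR only), ICCs use non-ranked data
    only, similarity uses raw non-ranked data, and group regressions skip the
    reinstatement-test (two data points cannot be correlated).
    """

    stimuli: tuple[str, ...] = ("CSP", "CSM", "DISC", "US")
    transforms: tuple[str, ...] = ("RAW", "LOG", "LOG_RC")
    ranked: tuple[bool, ...] = (False, True)
    analyses: tuple[str, ...] = (
        "internal_consistency", "icc_abs", "icc_con", "similarity",
        "group_regression", "cross_phase",
    )
    ic_phases: tuple[str, ...] = ("ACQ", "EXT", "RITEST")
    similarity_phases: tuple[str, ...] = ("ACQ", "EXT")
    group_phases: tuple[str, ...] = ("ACQ", "EXT")
    icc_codes: tuple[str, ...] = (
        "AVE_ACQ", "LAST2_ACQ", "FIRST_EXT", "AVE_EXT", "LAST2_EXT", "FIRST_RITEST",
    )
    prediction_pairs: tuple = field(
        default_factory=lambda: tuple(crossphase.default_prediction_pairs())
    )

    def __post_init__(self) -> None:
        bad = set(self.analyses) - set(ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses: {sorted(bad)}")


def default_grid() -> SpecGrid:
    return SpecGrid()


def _cells(grid: SpecGrid):
    """Yield (analysis, timepoint, phase_code, stimulus, transform, ranked)."""
    for analysis in grid.analyses:
        if analysis == "internal_consistency":
            for tp in ("T0", "T1"):
                for phase in grid.ic_phases:
                    for stim in grid.stimuli:
                        phases = ("ACQ", "RI") if stim == "US" else (phase,)
                        if stim == "US" and phase != "ACQ":
                            continue  # US trials exist in ACQ and RI only
                        for ph in phases:
                            for tr in grid.transforms:
                                yield (analysis, tp, ph, stim, tr, False)
        elif analysis in ("icc_abs", "icc_con"):
            for stim in grid.stimuli:
                codes = ("AVE_RI",) if stim == "US" else grid.icc_codes
                for code in codes:
                    for tr in grid.transforms:
                        yield (analysis, "both", code, stim, tr, False)
        elif analysis == "similarity":
            for phase in grid.similarity_phases:
                for stim in grid.stimuli:
                    if stim == "US" and phase != "ACQ":
                        continue  # no US during extinction training
                    yield (analysis, "both", phase, stim, "RAW", False)
        elif analysis == "group_regression":
            for phase in grid.group_phases:
                for stim in grid.stimuli:
                    if stim == "US" and phase != "ACQ":
                        continue
                    for tr in grid.transforms:
                        yield (analysis, "both", phase, stim, tr, False)
        elif analysis == "cross_phase":
            for pred, crit in grid.prediction_pairs:
                for stim in ("CSP", "CSM", "DISC"):
                    for tr in grid.transforms:
                        for rk in grid.ranked:
                            yield (analysis, "T0", f"{pred}->{crit}", stim, tr, rk)


def _similarity_vectors(table: pd.DataFrame, phase: str, stimulus: str):
    """Aligned (n, m) trial matrices at T0 and T1 for one phase/stimulus."""
    sub = table[table["phase"] == phase]
    if "role" in sub.columns:
        sub = sub[sub["role"] == "retained"]
    if stimulus == "DISC":
        sub = transforms.cs_discrimination(sub)
    else:
        sub = sub[sub["stimulus"] == stimulus]
    wide = sub.pivot_table(index="participant", columns=["timepoint", "trial"],
                           values="value")
    t0 = wide["T0"].dropna(axis=0)
    t1 = wide["T1"].dropna(axis=0)
    common = t0.index.intersection(t1.index)
    return t0.loc[common].to_numpy(), t1.loc[common].to_numpy(), list(common)


def run_multiverse(table: pd.DataFrame, ratings: pd.DataFrame | None = None,
                   grid: SpecGrid | None = None) -> pd.DataFrame:
    """Run the full specification grid on a scored trial-level table.

    The input is validated, trial exclusions are applied once, each
    transformation rung is materialized once, and every enumerated cell is
    executed; failures are captured per cell with a reason string. One output
    row per cell; deterministic given the inputs.
    """
    _validate_schema(table)
    grid = grid or default_grid()
    base = apply_trial_exclusions(table)
    tables = {tr: transforms.apply_transform(base, tr) for tr in set(grid.transforms) | {"RAW"}}

    measure_cache: dict[tuple[str, bool], pd.DataFrame] = {}

    def measures_for(tr: str, ranked: bool) -> pd.DataFrame:
        key = (tr, ranked)
        if key not in measure_cache:
            m = transforms.phase_measures(tables[tr], ratings)
            if ranked:
                m = transforms.rank_phase_measures(m)
            m["transform"] = tr
            m["ranked"] = ranked
            measure_cache[key] = m
        return measure_cache[key]

    rows = []
    for analysis, tp, code, stim, tr, rk in _cells(grid):
        row = dict.fromkeys(RESULT_COLUMNS)
        row.update(analysis=analysis, timepoint=tp, phase_code=code,
                   stimulus=stim, transform=tr, ranked=rk)
        try:
            if analysis == "internal_consistency":
                res = reliability.internal_consistency_odd_even(tables[tr], code, stim, tp)
                row.update(estimate=res.r, ci_low=res.ci_low, ci_high=res.ci_high,
                           n=res.n, benchmark=classify_benchmark(res.r, "internal_consistency"))
            elif analysis in ("icc_abs", "icc_con"):
                mtab = measures_for(tr, False)
                res = reliability.icc_from_measures(mtab, code, stim,
                                                    icc_type=analysis.split("_")[1])
                row.update(estimate=res.estimate, ci_low=res.ci_low, ci_high=res.ci_high,
                           n=res.n, benchmark=classify_benchmark(res.estimate, "icc"))
            elif analysis == "similarity":
                t0, t1, _ = _similarity_vectors(tables[tr], code, stim)
                sim = reliability.within_between_similarity(t0, t1)
                cmp_res = reliability.compare_similarity(sim.within_z, sim.between_z)
                row.update(estimate=float(sim.within_z.mean() - sim.between_z.mean()),
                           stat=cmp_res.statistic, p=cmp_res.p, n=cmp_res.n)
            elif analysis == "group_regression":
                res = groupstats.group_trial_regression(tables[tr], code, stim)
                row.update(estimate=res.r_squared, stat=res.f_stat, p=res.p, n=res.n)
            elif analysis == "cross_phase":
                pred, crit = code.split("->")
                spec = crossphase.PredictionSpec(pred, crit, stim, tr, rk)
                cell = crossphase.predict_grid(measures_for(tr, rk), [spec]).iloc[0]
                if cell["error"]:
                    raise ValueError(cell["error"])
                row.update(estimate=cell["beta_std"], stat=cell["t"], p=cell["p"],
                           n=cell["n"])
            else:
                raise ValueError(f"analysis {analysis!r} needs statistic maps; "
                                 "use the maps/groupstats API directly")
        except (ValueError, KeyError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return out


def _validate_schema(table: pd.DataFrame) -> None:
    required = {"participant", "timepoint", "phase", "stimulus", "trial", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"response table is missing columns: {sorted(missing)}")
    bad_tp = set(table["timepoint"].unique()) - {"T0", "T1"}
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    bad_stim = set(table["stimulus"].unique()) - {"CSP", "CSM", "US"}
    if bad_stim:
        raise ValueError(f"unknown stimuli: {sorted(bad_stim)}")
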