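"""Reading and writing the tidy CSV / NIfTI artifacts."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import cohort as _cohort
from .maps import BinaryMask, StatMap, load_stat_map, to_nifti
from .paradigm import ParadigmSpec, PhaseTrials

SCR_COLUMNS = ["participant", "timepoint", "day", "phase", "stimulus", "trial", "value", "valid"]
RATING_COLUMNS = ["participant", "timepoint", "occasion", "stimulus", "value"]


def write_response_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_response_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str, "timepoint": str,
                                  "phase": str, "stimulus": str})
    missing = set(SCR_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"response table at {path} is missing columns {sorted(missing)}")
    if "valid" not in df.columns:
        df["valid"] = True
    return df


def write_ratings(ratings: pd.DataFrame, path) -> None:
    ratings.to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str, "timepoint": str,
                                  "occasion": str, "stimulus": str})
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rating table at {path} is missing columns {sorted(missing)}")
    return df


def save_map(m: StatMap | BinaryMask, path) -> None:
    to_nifti(m).to_filename(str(path))


load_map = load_stat_map


def load_cohort_config(path) -> _cohort.CohortConfig:
    """Build a CohortConfig from a YAML file; unspecified blocks use the
    package defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "paradigm" in raw:
        p = raw["paradigm"]
        kwargs["paradigm"] = ParadigmSpec(
            phases=tuple(p["phases"]),
            trials_per_phase={ph: PhaseTrials(**c) for ph, c in p["trials_per_phase"].items()},
            day_of_phase={ph: int(d) for ph, d in p["day_of_phase"].items()},
            reinforcement=float(p.get("reinforcement", 1.0)),
        )
    if "components" in raw:
        comps = _cohort.default_components()
        for stim, c in raw["components"].items():
            comps[stim] = _cohort.VarianceComponents(**c)
        kwargs["components"] = comps
    for key in ("n_participants", "seed", "nonresponder_fraction"):
        if key in raw:
            kwargs[key] = raw[key]
    return _cohort.CohortConfig(**kwargs)
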