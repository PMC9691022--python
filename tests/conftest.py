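import numpy as np
import pandas as pd
import pytest

from condrel import CohortConfig, VarianceComponents, simulate_cohort
from condrel.paradigm import ParadigmSpec, PhaseTrials


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant default-paradigm cohort (SCR table, ratings)."""
    return simulate_cohort(CohortConfig(n_participants=12, seed=7))


@pytest.fixture(scope="session")
def acq_only_paradigm():
    return ParadigmSpec(phases=("ACQ",),
                        trials_per_phase={"ACQ": PhaseTrials(14, 14, 14)},
                        day_of_phase={"ACQ": 1})


def make_us_table(n_zero_acq: int, ri_values=(0.2, 0.3, 0.1)) -> pd.DataFrame:
    """One participant's US trials: 14 in acquisition (n_zero_acq of them
    zero) and 3 reinstatement USs."""
    acq_vals = np.concatenate([np.zeros(n_zero_acq), np.full(14 - n_zero_acq, 0.5)])
    rows = [{"participant": "P1", "timepoint": "T0", "day": 1, "phase": "ACQ",
             "stimulus": "US", "trial": i + 1, "value": v, "valid": True}
            for i, v in enumerate(acq_vals)]
    rows += [{"participant": "P1", "timepoint": "T0", "day": 2, "phase": "RI",
              "stimulus": "US", "trial": i + 1, "value": v, "valid": True}
             for i, v in enumerate(ri_values)]
    return pd.DataFrame(rows)
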