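"""Experimental paradigm description for a 2-day, two-timepoint differential
fear-conditioning protocol.

The default protocol has habituation and acquisition training on day 1 and
extinction training, reinstatement, and reinstatement-test on day 2, run
identically at two timepoints (T0, T1) six months apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PHASES = ("HAB", "ACQ", "EXT", "RI", "RITEST")
STIMULI = ("CSP", "CSM", "US")
TIMEPOINTS = ("T0", "T1")


@dataclass(frozen=True)
class PhaseTrials:
    """Trial counts for one phase, per stimulus class."""

    csp: int = 0
    csm: int = 0
    us: int = 0

    def count(self, stimulus: str) -> int:
        return {"CSP": self.csp, "CSM": self.csm, "US": self.us}[stimulus]


@dataclass(frozen=True)
class ParadigmSpec:
    """Ordered phases, trial counts, day assignment and reinforcement rate.

    ``reinforcement`` is the fraction of acquisition CS+ trials followed by
    the aversive US (1.0 = delay conditioning with 100% reinforcement).
    """

    phases: tuple[str, ...] = PHASES
    trials_per_phase: dict[str, PhaseTrials] = field(default_factory=dict)
    day_of_phase: dict[str, int] = field(default_factory=dict)
    reinforcement: float = 1.0

    def __post_init__(self) -> None:
        for ph in self.phases:
            if ph not in self.trials_per_phase:
                raise ValueError(f"no trial counts for phase {ph!r}")
            if self.day_of_phase.get(ph) not in (1, 2):
                raise ValueError(f"phase {ph!r} must be assigned to day 1 or 2")
        if not 0.0 <= self.reinforcement <= 1.0:
            raise ValueError("reinforcement must be in [0, 1]")


def default_paradigm() -> ParadigmSpec:
    """The 2-day protocol: HAB 7+7, ACQ 14 CS+/14 CS- (fully reinforced, 14
    US), EXT 14+14, reinstatement 3 US-only trials, RI-Test 7+7."""
    return ParadigmSpec(
        phases=PHASES,
        trials_per_phase={
            "HAB": PhaseTrials(7, 7, 0),
            "ACQ": PhaseTrials(14, 14, 14),
            "EXT": PhaseTrials(14, 14, 0),
            "RI": PhaseTrials(0, 0, 3),
            "RITEST": PhaseTrials(7, 7, 0),
        },
        day_of_phase={"HAB": 1, "ACQ": 1, "EXT": 2, "RI": 2, "RITEST": 2},
        reinforcement=1.0,
    )
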