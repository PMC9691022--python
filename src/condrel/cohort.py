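"""Synthetic two-timepoint fear-conditioning cohorts with known ground truth.

The generator produces trial-level skin-conductance amplitude tables, a
companion fear-rating table and paired 3D statistic maps whose reliability
structure is controlled exactly, so every downstream analysis can be checked
against closed-form expectations.

Amplitude model, per stimulus class::

    value = max(0, mu + trend(phase, trial) + b_subject + b_subject_session + eps)

with ``b_subject ~ N(0, sigma_subject^2)`` stable across timepoints,
``b_subject_session ~ N(0, sigma_subject_session^2)`` redrawn per timepoint,
trial noise ``eps ~ N(0, sigma_trial^2)``, and an explicit Bernoulli
zero-inflation: each trial is floored to exactly 0 with probability
``zero_p``. Under this decomposition the intraclass correlation of the mean
over m trials is the closed form returned by :func:`true_icc`.

One RNG stream per participant keyed by ``(seed, participant_index)`` keeps
existing participants' data unchanged when the cohort grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import StatMap
from .paradigm import ParadigmSpec, STIMULI, TIMEPOINTS, default_paradigm

__all__ = [
    "VarianceComponents",
    "CohortConfig",
    "default_components",
    "simulate_cohort",
    "true_icc",
    "simulate_stat_map_pair",
]

RATING_OCCASIONS = ("PRE_ACQ", "POST_ACQ", "PRE_EXT", "POST_EXT", "POST_RITEST")

#: Population means of the 0-25 fear ratings per (stimulus, occasion); the
#: CS+ rises with acquisition and wanes with extinction, the CS- stays low,
#: US aversiveness is high throughout.
DEFAULT_RATING_MEANS = {
    ("CSP", "PRE_ACQ"): 5.0,
    ("CSP", "POST_ACQ"): 18.0,
    ("CSP", "PRE_EXT"): 14.0,
    ("CSP", "POST_EXT"): 7.0,
    ("CSP", "POST_RITEST"): 10.0,
    ("CSM", "PRE_ACQ"): 5.0,
    ("CSM", "POST_ACQ"): 4.0,
    ("CSM", "PRE_EXT"): 4.0,
    ("CSM", "POST_EXT"): 3.0,
    ("CSM", "POST_RITEST"): 3.0,
    ("US", "POST_ACQ"): 20.0,
    ("US", "POST_RITEST"): 17.0,
}


@dataclass(frozen=True)
class VarianceComponents:
    """Variance decomposition and deterministic trend of one stimulus class.

    mu : baseline mean amplitude (uS).
    sigma_subject : SD of the stable subject effect (between-subject).
    sigma_subject_session : SD of the subject-by-timepoint effect.
    sigma_trial : SD of trial-level noise.
    zero_p : probability that a trial is floored to exactly zero.
    learning_gain : asymptote (uS) of the CS+ acquisition ramp; also the
        starting height of the extinction decay.
    extinction_decay : exponential decay rate per extinction trial.
    us_gain : additive mean response to the US.
    """

    mu: float = 0.3
    sigma_subject: float = 0.25
    sigma_subject_session: float = 0.15
    sigma_trial: float = 0.25
    zero_p: float = 0.1
    learning_gain: float = 0.0
    extinction_decay: float = 0.3
    us_gain: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_subject", "sigma_subject_session", "sigma_trial"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.zero_p <= 1.0:
            raise ValueError("zero_p must be in [0, 1]")


def default_components() -> dict[str, VarianceComponents]:
    """Per-stimulus defaults: CS+ with an acquisition ramp, flat CS-, large US."""
    return {
        "CSP": VarianceComponents(mu=0.3, learning_gain=0.4),
        "CSM": VarianceComponents(mu=0.3),
        "US": VarianceComponents(mu=0.3, us_gain=0.8, zero_p=0.05),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to simulate one cohort deterministically."""

    n_participants: int
    paradigm: ParadigmSpec = field(default_factory=default_paradigm)
    components: dict[str, VarianceComponents] = field(default_factory=default_components)
    seed: int = 0
    nonresponder_fraction: float = 0.0
    rating_sigma_subject: float = 3.0
    rating_sigma_noise: float = 2.0
    rating_means: dict = field(default_factory=lambda: dict(DEFAULT_RATING_MEANS))

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("a cohort needs at least 2 participants")
        if not 0.0 <= self.nonresponder_fraction <= 1.0:
            raise ValueError("nonresponder_fraction must be in [0, 1]")


def _trend(comp: VarianceComponents, phase: str, stimulus: str, trials: np.ndarray) -> np.ndarray:
    """Deterministic phase trend: linear ramp saturating at learning_gain in
    acquisition, exponential decay from that height in extinction."""
    if stimulus == "US":
        return np.full(trials.shape, comp.us_gain)
    if phase == "ACQ":
        ramp = 5.0  # trials to reach the asymptote
        return comp.learning_gain * np.minimum(1.0, (trials - 1) / ramp)
    if phase == "EXT":
        return comp.learning_gain * np.exp(-comp.extinction_decay * (trials - 1))
    return np.zeros(trials.shape)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the trial-level SCR table and the companion rating table.

    Returns a tidy SCR table with one row per participant x timepoint x phase
    x stimulus x trial (columns: participant, timepoint, day, phase, stimulus,
    trial, value, valid) and a rating table with one row per participant x
    timepoint x rating occasion x stimulus (value on the 0-25 scale).
    Deterministic given ``config.seed``.
    """
    par = config.paradigm
    n_digits = max(3, len(str(config.n_participants)))
    cols: dict[str, list] = {k: [] for k in
                             ("participant", "timepoint", "day", "phase", "stimulus", "trial", "value")}
    rcols: dict[str, list] = {k: [] for k in
                              ("participant", "timepoint", "occasion", "stimulus", "value")}

    for i in range(config.n_participants):
        pid = f"P{i + 1:0{n_digits}d}"
        rng = np.random.default_rng([config.seed, i])
        nonresponder = rng.random() < config.nonresponder_fraction
        # subject effects, one per stimulus class, stable across timepoints
        b_subj = {s: rng.normal(0.0, config.components[s].sigma_subject) for s in STIMULI}
        b_sess = {
            (s, tp): rng.normal(0.0, config.components[s].sigma_subject_session)
            for s in STIMULI
            for tp in TIMEPOINTS
        }
        b_subj_rating = rng.normal(0.0, config.rating_sigma_subject)

        for tp in TIMEPOINTS:
            for phase in par.phases:
                counts = par.trials_per_phase[phase]
                day = par.day_of_phase[phase]
                for stim in STIMULI:
                    n_tr = counts.count(stim)
                    if n_tr == 0:
                        continue
                    comp = config.components[stim]
                    trials = np.arange(1, n_tr + 1, dtype=float)
                    mean = comp.mu + _trend(comp, phase, stim, trials) + b_subj[stim] + b_sess[(stim, tp)]
                    vals = np.maximum(0.0, mean + rng.normal(0.0, comp.sigma_trial, n_tr))
                    vals[rng.random(n_tr) < comp.zero_p] = 0.0
                    if nonresponder and stim == "US":
                        vals[:] = 0.0
                    cols["participant"].append(np.repeat(pid, n_tr))
                    cols["timepoint"].append(np.repeat(tp, n_tr))
                    cols["day"].append(np.repeat(day, n_tr))
                    cols["phase"].append(np.repeat(phase, n_tr))
                    cols["stimulus"].append(np.repeat(stim, n_tr))
                    cols["trial"].append(np.arange(1, n_tr + 1))
                    cols["value"].append(vals)
            # ratings for this timepoint, discretized latent Gaussian on 0-25
            for (stim, occ), mu_r in config.rating_means.items():
                latent = mu_r + b_subj_rating + rng.normal(0.0, config.rating_sigma_noise)
                rcols["participant"].append(pid)
                rcols["timepoint"].append(tp)
                rcols["occasion"].append(occ)
                rcols["stimulus"].append(stim)
                rcols["value"].append(float(np.clip(np.rint(latent), 0, 25)))

    scr = pd.DataFrame({k: np.concatenate(v) if v else np.array([]) for k, v in cols.items()})
    scr["day"] = scr["day"].astype(int)
    scr["trial"] = scr["trial"].astype(int)
    scr["value"] = scr["value"].astype(float)
    scr["valid"] = True
    ratings = pd.DataFrame(rcols)
    return scr, ratings


def true_icc(components: VarianceComponents, m: int = 1) -> float:
    """Closed-form ICC of the mean over m trials implied by the components:
    sigma_s^2 / (sigma_s^2 + sigma_ss^2 + sigma_t^2 / m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    num = components.sigma_subject ** 2
    denom = num + components.sigma_subject_session ** 2 + components.sigma_trial ** 2 / m
    if denom == 0.0:
        raise ValueError("ICC undefined: all variance components are zero")
    return num / denom


def simulate_stat_map_pair(
    shape: tuple[int, int, int],
    rho: float,
    df: int = 70,
    seed: int = 0,
    kind: str = "t",
    scale: float = 1.0,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> tuple[StatMap, StatMap]:
    """Two maps whose voxel values are bivariate Gaussian with correlation rho.

    The sample correlation of the voxel vectors converges to rho as the voxel
    count grows. ``df`` is recorded on both maps.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    if any(d <= 0 for d in shape):
        raise ValueError("map dimensions must be positive")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(shape)
    z2 = rng.standard_normal(shape)
    a = scale * z1
    b = scale * (rho * z1 + math.sqrt(1.0 - rho ** 2) * z2)
    return (
        StatMap(a, df=df, kind=kind, voxel_size=voxel_size),
        StatMap(b, df=df, kind=kind, voxel_size=voxel_size),
    )
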