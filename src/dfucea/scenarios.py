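"""Scenario generation and validation oracles.

Three roles:

* :func:`generate_base_case` — the canonical parameter set: the published
  weekly transition probabilities, unit costs, economic settings and +/-20%
  sensitivity ranges, with the calibrated utility defaults. A YAML copy is
  shipped at ``dfucea/data/base_case.yaml`` and must round-trip to the same
  values.
* :func:`generate_toy_scenario` — small round-number scenarios carrying
  their own closed-form expectations (eventual amputation fraction, expected
  weeks with an open ulcer), for analytic tests of the cohort engine.
* :func:`microsim_oracle` — a seeded individual-level microsimulation that
  draws each patient's weekly multinomial transitions from exactly the rows
  the cohort engine uses; its mean occupancies (with Monte Carlo standard
  errors) are an independent brute-force check of the deterministic trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .markov import DEAD_AMP, DEAD_DISEASE, HEALED, OPEN, POST_AMP, STATES, _transition_matrix
from .parameters import (
    CONVENTIONAL,
    RHEGF,
    ParameterSet,
    SharedParams,
    StrategyParams,
    default_ranges,
    load_parameters,
)


def generate_base_case() -> ParameterSet:
    """The canonical base-case parameter set (both strategies, all ranges)."""
    strategies = {
        RHEGF: StrategyParams(
            name=RHEGF, p_closure_week=0.0398, p_amputation_week=0.0164,
            treatment_duration_weeks=8, vials_per_week=3),
        CONVENTIONAL: StrategyParams(
            name=CONVENTIONAL, p_closure_week=0.0129, p_amputation_week=0.0308,
            treatment_duration_weeks=260, weekly_drug_cost=0.0),
    }
    ps = ParameterSet(strategies=strategies)
    ps.ranges = default_ranges(ps)
    return ps.raise_if_invalid()


def base_case_file():
    """Path-like handle to the shipped canonical parameter YAML."""
    return resources.files("dfucea").joinpath("data/base_case.yaml")


def load_base_case_file() -> ParameterSet:
    """Load the shipped base-case YAML (round-trips generate_base_case)."""
    with base_case_file().open("r", encoding="utf-8") as fh:
        return load_parameters(fh)


@dataclass
class ToyScenario:
    """A small scenario with analytically known outcomes.

    With constant competing weekly probabilities out of the open state, the
    exit process is geometric: the eventual amputation fraction is
    ``p_amp / (p_close + p_amp + p_death)`` and the expected number of weeks
    with an open ulcer is ``1 / (p_close + p_amp + p_death)`` (infinite
    horizon).
    """

    params: ParameterSet
    eventual_amputation_fraction: float
    expected_open_weeks: float
    infinite_duration: bool = False

    def __post_init__(self):
        s = self.params.strategies["toy"]
        total = (s.p_closure_week + s.p_amputation_week
                 + self.params.shared.p_death_disease_week)
        if total == 0:
            assert self.infinite_duration
        else:
            assert abs(self.eventual_amputation_fraction
                       - s.p_amputation_week / total) < 1e-12
            assert abs(self.expected_open_weeks - 1.0 / total) < 1e-12


def generate_toy_scenario(p_close: float, p_amp: float,
                          p_death: float = 0.0,
                          horizon_weeks: int = 260) -> ToyScenario:
    """A single-arm scenario with closed-form expected outcomes attached."""
    shared = SharedParams(p_death_disease_week=p_death,
                          p_death_amputation_event=0.0,
                          annual_discount_rate=0.0,
                          horizon_weeks=horizon_weeks)
    params = ParameterSet(strategies={
        "toy": StrategyParams(name="toy", p_closure_week=p_close,
                              p_amputation_week=p_amp,
                              treatment_duration_weeks=1)},
        shared=shared)
    params.raise_if_invalid()
    total = p_close + p_amp + p_death
    if total == 0:
        return ToyScenario(params=params, eventual_amputation_fraction=0.0,
                           expected_open_weeks=float("inf"),
                           infinite_duration=True)
    return ToyScenario(params=params,
                       eventual_amputation_fraction=p_amp / total,
                       expected_open_weeks=1.0 / total)


@dataclass
class MicrosimResult:
    """Aggregated individual-level simulation output.

    ``occupancy_mean[w, s]`` estimates the cohort occupancy; ``occupancy_se``
    is its binomial Monte Carlo standard error. Per-patient event weeks
    (first closure / amputation / death; -1 = never) summarise each
    simulated trajectory.
    """

    strategy: str
    n_patients: int
    seed: int
    occupancy_mean: np.ndarray
    occupancy_se: np.ndarray
    amputations_per_patient: float
    amputations_se: float
    closure_week: np.ndarray
    amputation_week: np.ndarray
    death_week: np.ndarray
    states: tuple[str, ...] = STATES


def microsim_oracle(strategy: StrategyParams, shared: SharedParams,
                    n_patients: int, seed: int) -> MicrosimResult:
    """Simulate patients one week at a time with the engine's own rows.

    Every patient starts with an open ulcer; each week their next state is a
    single multinomial draw from the transition row of their current state —
    the same rows the cohort engine multiplies through. Vectorised over
    patients; one child RNG stream per run derived from ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    H = shared.horizon_weeks

    onset = max(strategy.closure_onset_week - 1, 0)
    M_pre = _transition_matrix(strategy, shared, week=0) if onset > 0 else None
    M_post = _transition_matrix(strategy, shared, week=onset)
    cum_pre = np.cumsum(M_pre, axis=1) if M_pre is not None else None
    cum_post = np.cumsum(M_post, axis=1)

    state = np.zeros(n_patients, dtype=np.int8)  # all open
    counts = np.zeros((H + 1, len(STATES)), dtype=np.int64)
    counts[0, OPEN] = n_patients
    closure_week = np.full(n_patients, -1, dtype=np.int32)
    amputation_week = np.full(n_patients, -1, dtype=np.int32)
    death_week = np.full(n_patients, -1, dtype=np.int32)
    amput_count = np.zeros(n_patients, dtype=np.int8)

    for w in range(H):
        cum = cum_pre if (cum_pre is not None and w < onset) else cum_post
        u = rng.random(n_patients)
        # row lookup per patient, inverse-CDF draw against that row
        new_state = (u[:, None] >= cum[state]).sum(axis=1).astype(np.int8)
        entered = new_state != state
        closure_week[entered & (new_state == HEALED)] = w + 1
        newly_amp = entered & ((new_state == POST_AMP) | (new_state == DEAD_AMP)) \
            & (state == OPEN)
        amputation_week[newly_amp] = w + 1
        amput_count[newly_amp] += 1
        died = entered & ((new_state == DEAD_DISEASE) | (new_state == DEAD_AMP))
        death_week[died] = w + 1
        state = new_state
        counts[w + 1] = np.bincount(state, minlength=len(STATES))

    mean = counts / n_patients
    se = np.sqrt(mean * (1 - mean) / n_patients)
    amp_mean = float(amput_count.mean())
    amp_se = float(amput_count.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0
    return MicrosimResult(
        strategy=strategy.name, n_patients=n_patients, seed=seed,
        occupancy_mean=mean, occupancy_se=se,
        amputations_per_patient=amp_mean, amputations_se=amp_se,
        closure_week=closure_week, amputation_week=amputation_week,
        death_week=death_week)
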