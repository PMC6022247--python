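"""Cost and QALY accrual over a cohort trace.

Accrual conventions (no half-cycle correction by default):

* weekly recurring costs are billed to the start-of-cycle open-ulcer
  occupancy and discounted at the billing week;
* one-off event costs (amputation surgery, prosthesis, rehabilitation) are
  billed to the event flow at the week the event lands;
* QALYs accrue 1/52 of the annual utility weight per week of end-of-cycle
  state occupancy.

The weekly wound-care bundle (the conventional-therapy components) is billed
to every arm while the ulcer is open — rhEGF is an adjuvant on top of
conventional care. Within an arm it is categorised as active treatment
(``drugs_and_therapy``) while the week index is inside the arm's treatment
window and as continued wound care of non-closed patients
(``procedures_nonclosure``) afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import HEALED, OPEN, POST_AMP, CohortTrace
from .parameters import (
    CostTable,
    ParameterSet,
    SharedParams,
    StrategyParams,
    UtilitySet,
    weekly_discount_factor,
)


class CalibrationError(RuntimeError):
    """No utility set in [0, 1] can reproduce the requested QALY targets."""


@dataclass
class CostBreakdown:
    """Per-patient accrued costs (USD) by category."""

    drugs_and_therapy: float
    amputee_costs: float
    procedures_nonclosure: float
    rehabilitation: float
    total: float
    discounted_total: float
    discounted_by_category: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "drugs_and_therapy": self.drugs_and_therapy,
            "amputee_costs": self.amputee_costs,
            "procedures_nonclosure": self.procedures_nonclosure,
            "rehabilitation": self.rehabilitation,
            "total": self.total,
            "discounted_total": self.discounted_total,
        }

    def shares(self) -> dict[str, float]:
        """Undiscounted category shares of the total (fractions)."""
        if self.total == 0:
            return {k: 0.0 for k in ("drugs_and_therapy", "amputee_costs",
                                     "procedures_nonclosure", "rehabilitation")}
        return {
            "drugs_and_therapy": self.drugs_and_therapy / self.total,
            "amputee_costs": self.amputee_costs / self.total,
            "procedures_nonclosure": self.procedures_nonclosure / self.total,
            "rehabilitation": self.rehabilitation / self.total,
        }


@dataclass
class QALYResult:
    qalys_undiscounted: float
    qalys_discounted: float


def accrue_costs(trace: CohortTrace, strategy: StrategyParams, costs: CostTable,
                 shared: SharedParams, include_conventional_care: bool = True,
                 half_cycle: bool = False) -> CostBreakdown:
    """Accrue per-patient costs for one arm.

    ``include_conventional_care`` bills the weekly wound-care bundle while the
    ulcer is open (on for every arm by default; off isolates the drug cost).
    ``half_cycle`` averages start/end occupancy for the weekly billing base.
    """
    H = trace.horizon_weeks
    weeks_start = np.arange(H)            # cycle billing weeks
    weeks_event = np.arange(H + 1)        # event landing weeks
    df_start = weekly_discount_factor(shared.annual_discount_rate, weeks_start)
    df_event = weekly_discount_factor(shared.annual_discount_rate, weeks_event)

    open_occ = trace.occupancy[:H, OPEN]
    if half_cycle:
        open_occ = 0.5 * (open_occ + trace.occupancy[1:, OPEN])
    in_window = weeks_start < strategy.treatment_duration_weeks

    weekly_care = costs.weekly_conventional_total if include_conventional_care else 0.0
    drug_weekly = strategy.weekly_drug_cost

    drugs_u = float((open_occ * in_window).sum() * drug_weekly
                    + (open_occ * in_window).sum() * weekly_care)
    drugs_d = float((open_occ * in_window * df_start).sum() * (drug_weekly + weekly_care))
    proc_u = float((open_occ * ~in_window).sum() * weekly_care)
    proc_d = float((open_occ * ~in_window * df_start).sum() * weekly_care)

    # amputation surgery billed per event (procedure deaths included: the
    # surgery happened); prosthesis billed per surviving amputee, mixing the
    # over/under-knee level split with the level-specific fitting rates.
    amputations = trace.flow_amputations
    survivors = amputations - trace.flow_deaths_amputation
    prosthesis_per_survivor = (
        shared.frac_amputations_over_knee
        * shared.frac_prosthesis_over_knee * costs.prosthesis_over_knee
        + (1.0 - shared.frac_amputations_over_knee)
        * shared.frac_prosthesis_under_knee * costs.prosthesis_under_knee)
    amputee_u = float(costs.amputation_procedure * amputations.sum()
                      + prosthesis_per_survivor * survivors.sum())
    amputee_d = float(costs.amputation_procedure * (amputations * df_event).sum()
                      + prosthesis_per_survivor * (survivors * df_event).sum())

    rehab_u = float(costs.rehabilitation_after_closure * trace.flow_closures.sum())
    rehab_d = float(costs.rehabilitation_after_closure
                    * (trace.flow_closures * df_event).sum())

    total = drugs_u + proc_u + amputee_u + rehab_u
    disc = {"drugs_and_therapy": drugs_d, "procedures_nonclosure": proc_d,
            "amputee_costs": amputee_d, "rehabilitation": rehab_d}
    return CostBreakdown(
        drugs_and_therapy=drugs_u, amputee_costs=amputee_u,
        procedures_nonclosure=proc_u, rehabilitation=rehab_u,
        total=total, discounted_total=float(sum(disc.values())),
        discounted_by_category=disc)


def state_person_years(trace: CohortTrace, shared: SharedParams,
                       discounted: bool = False,
                       half_cycle: bool = False) -> np.ndarray:
    """Person-years per alive state (open, healed, post-amputation)."""
    occ = trace.occupancy[1:, [OPEN, HEALED, POST_AMP]]
    if half_cycle:
        occ = 0.5 * (occ + trace.occupancy[:-1, [OPEN, HEALED, POST_AMP]])
    if discounted:
        weeks = np.arange(1, trace.horizon_weeks + 1)
        occ = occ * weekly_discount_factor(
            shared.annual_discount_rate, weeks)[:, None]
    return occ.sum(axis=0) / 52.0


def accrue_qalys(trace: CohortTrace, utilities: UtilitySet, shared: SharedParams,
                 half_cycle: bool = False) -> QALYResult:
    """Quality-adjusted life years for one arm, discounted and not."""
    u = np.array([utilities.u_open_ulcer, utilities.u_healed,
                  utilities.u_post_amputation])
    y_u = state_person_years(trace, shared, discounted=False, half_cycle=half_cycle)
    y_d = state_person_years(trace, shared, discounted=True, half_cycle=half_cycle)
    return QALYResult(qalys_undiscounted=float(y_u @ u),
                      qalys_discounted=float(y_d @ u))


def calibrate_utilities(target_qalys_by_arm: dict[str, float],
                        params: ParameterSet,
                        u_healed: float = 1.0,
                        tol: float = 1e-3) -> tuple[UtilitySet, dict]:
    """Solve for (u_open, u_post_amputation) hitting per-arm QALY targets.

    Because QALYs are linear in the utility weights, fixing ``u_healed``
    leaves a 2x2 linear system in the other two weights, built from each
    arm's state person-years. The solution is unique given ``u_healed`` but
    the full problem is a one-parameter family over ``u_healed``: the info
    dict reports the feasible ``u_healed`` interval, and an infeasible fixed
    value raises :class:`CalibrationError` quoting that interval.

    ``target_qalys_by_arm`` maps strategy name to undiscounted QALYs.
    """
    from .markov import run_cohort  # local import to avoid cycle at import time

    horizon_years = params.shared.horizon_weeks / 52.0
    names = list(target_qalys_by_arm)
    if len(names) != 2:
        raise CalibrationError("exactly two arm targets are required")
    for name, t in target_qalys_by_arm.items():
        if not 0 < t <= horizon_years:
            raise CalibrationError(
                f"target for {name!r} must be in (0, {horizon_years}] years, got {t}")

    Y = np.zeros((2, 3))  # rows: arms; cols: open, healed, post
    for i, name in enumerate(names):
        trace = run_cohort(params.strategies[name], params.shared)
        Y[i] = state_person_years(trace, params.shared)
    targets = np.array([target_qalys_by_arm[n] for n in names])

    A = Y[:, [0, 2]]
    if abs(np.linalg.det(A)) < 1e-12:
        raise CalibrationError("arm person-year profiles are degenerate; "
                               "targets do not identify the utilities")

    def solve(uh: float) -> np.ndarray:
        return np.linalg.solve(A, targets - uh * Y[:, 1])

    # feasible u_healed interval: each of u_open(uh), u_post(uh) is affine in
    # uh, so the feasible set is an interval found from the four constraints.
    base = solve(0.0)
    slope = solve(1.0) - base
    lo, hi = 0.0, 1.0
    for b, s in zip(base, slope):
        if abs(s) < 1e-15:
            if not 0 <= b <= 1:
                lo, hi = 1.0, 0.0
            continue
        bounds = sorted(((0 - b) / s, (1 - b) / s))
        lo, hi = max(lo, bounds[0]), min(hi, bounds[1])
    feasible = (lo, hi) if lo <= hi else None

    u_open, u_post = solve(u_healed)
    info = {
        "person_years": {n: Y[i].tolist() for i, n in enumerate(names)},
        "feasible_u_healed": feasible,
        "non_uniqueness": (
            "solution is unique only conditional on u_healed; the full "
            "calibration is a one-parameter family over u_healed"
        ),
    }
    eps = 1e-9
    if not (-eps <= u_open <= 1 + eps and -eps <= u_post <= 1 + eps):
        msg = (f"no feasible utilities at u_healed={u_healed}: "
               f"u_open={u_open:.4f}, u_post_amputation={u_post:.4f}; ")
        msg += ("feasible u_healed interval is "
                f"[{feasible[0]:.4f}, {feasible[1]:.4f}]" if feasible
                else "no u_healed in [0, 1] is feasible")
        raise CalibrationError(msg)

    result = UtilitySet(u_open_ulcer=float(np.clip(u_open, 0, 1)),
                        u_healed=float(u_healed),
                        u_post_amputation=float(np.clip(u_post, 0, 1)))
    # self-check: forward model must reproduce the targets
    for i, name in enumerate(names):
        achieved = float(Y[i] @ np.array([result.u_open_ulcer, result.u_healed,
                                          result.u_post_amputation]))
        if abs(achieved - targets[i]) > tol:
            raise CalibrationError(
                f"calibration residual {achieved - targets[i]:.2e} for {name!r} "
                f"exceeds tolerance {tol}")
    return result, info
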