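"""Incremental cost-effectiveness statistics and CE-plane classification.

The ICER is the standard Delta-cost / Delta-effect ratio in USD per QALY (or
per amputation averted), compared against a willingness-to-pay threshold of
``threshold_multiplier`` x GDP per capita. CE-plane categories for the new
strategy versus the reference:

* ``dominant`` — cheaper and more effective;
* ``cost_effective_below_threshold`` — more costly and more effective with
  ICER <= threshold (or cost-saving per QALY lost above the threshold in the
  rare south-west quadrant);
* ``above_threshold`` — more costly and more effective with ICER > threshold;
* ``dominated`` — more costly and less (or equally) effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .markov import expected_amputations, expected_amputations_discounted, run_cohort
from .outcomes import accrue_costs, accrue_qalys
from .parameters import CONVENTIONAL, RHEGF, ParameterSet, SharedParams

DOMINANT = "dominant"
BELOW = "cost_effective_below_threshold"
ABOVE = "above_threshold"
DOMINATED = "dominated"
CATEGORIES = (DOMINANT, BELOW, ABOVE, DOMINATED)


@dataclass
class CEResult:
    delta_cost: float
    delta_effect: float
    icer: float | None
    threshold: float
    category: str


def threshold_usd(shared: SharedParams) -> float:
    """Willingness-to-pay threshold: multiplier x GDP per capita (USD/QALY)."""
    return shared.threshold_multiplier * shared.gdp_per_capita_usd


def usd_to_cop(amount_usd: float, shared: SharedParams) -> float:
    """Convert USD to Colombian pesos at the configured exchange rate."""
    return amount_usd * shared.cop_per_usd


def classify(delta_cost: float, delta_effect: float, threshold: float) -> str:
    """CE-plane category of (delta_effect, delta_cost) at a threshold."""
    if delta_effect > 0:
        if delta_cost <= 0:
            return DOMINANT
        return BELOW if delta_cost / delta_effect <= threshold else ABOVE
    if delta_effect < 0:
        if delta_cost >= 0:
            return DOMINATED
        # south-west: cost-saving at the price of lost effect
        return BELOW if delta_cost / delta_effect > threshold else ABOVE
    # zero effect difference: resolved by cost sign alone
    if delta_cost > 0:
        return DOMINATED
    if delta_cost < 0:
        return DOMINANT
    return BELOW


def icer(cost_new: float, cost_ref: float, effect_new: float, effect_ref: float,
         threshold: float = math.inf) -> CEResult:
    """Incremental cost-effectiveness of the new strategy vs the reference.

    The ratio is undefined (``None``) when the effect difference is zero; the
    category then follows the cost sign alone.
    """
    d_cost = cost_new - cost_ref
    d_eff = effect_new - effect_ref
    ratio = d_cost / d_eff if d_eff != 0 else None
    return CEResult(delta_cost=d_cost, delta_effect=d_eff, icer=ratio,
                    threshold=threshold,
                    category=classify(d_cost, d_eff, threshold))


def compare_strategies(params: ParameterSet, new: str = RHEGF,
                       ref: str = CONVENTIONAL,
                       effect: str = "qalys") -> dict:
    """Run both arms end-to-end and assemble per-arm plus incremental results.

    Returns a plain dict (JSON-ready) with per-arm amputations, QALYs and
    cost breakdowns (discounted and undiscounted) and the incremental
    :class:`CEResult` on the discounted scale. ``effect`` selects the ICER
    denominator: ``"qalys"`` or ``"amputations_averted"``.
    """
    params.raise_if_invalid()
    thr = threshold_usd(params.shared)
    arms: dict[str, dict] = {}
    for name in (new, ref):
        strat = params.strategies[name]
        trace = run_cohort(strat, params.shared)
        costs = accrue_costs(trace, strat, params.costs, params.shared)
        qalys = accrue_qalys(trace, params.utilities, params.shared)
        arms[name] = {
            "amputations": expected_amputations(trace),
            "amputations_discounted": expected_amputations_discounted(
                trace, params.shared),
            "amputations_discounted_end_of_horizon": expected_amputations_discounted(
                trace, params.shared, method="end_of_horizon"),
            "qalys": qalys.qalys_undiscounted,
            "qalys_discounted": qalys.qalys_discounted,
            "cost_total": costs.total,
            "cost_total_discounted": costs.discounted_total,
            "cost_breakdown": costs.as_dict(),
            "cost_shares": costs.shares(),
        }
    if effect == "qalys":
        eff_new, eff_ref = arms[new]["qalys_discounted"], arms[ref]["qalys_discounted"]
    elif effect == "amputations_averted":
        eff_new = -arms[new]["amputations_discounted"]
        eff_ref = -arms[ref]["amputations_discounted"]
    else:
        raise ValueError(f"unknown effect measure {effect!r}")
    ce = icer(arms[new]["cost_total_discounted"], arms[ref]["cost_total_discounted"],
              eff_new, eff_ref, threshold=thr)
    return {
        "arms": arms,
        "incremental": {
            "new": new,
            "reference": ref,
            "effect_measure": effect,
            "amputations_averted": arms[ref]["amputations"] - arms[new]["amputations"],
            "amputations_averted_discounted": (
                arms[ref]["amputations_discounted"] - arms[new]["amputations_discounted"]),
            "amputations_averted_discounted_end_of_horizon": (
                arms[ref]["amputations_discounted_end_of_horizon"]
                - arms[new]["amputations_discounted_end_of_horizon"]),
            "qalys_gained": arms[new]["qalys"] - arms[ref]["qalys"],
            "qalys_gained_discounted": (
                arms[new]["qalys_discounted"] - arms[ref]["qalys_discounted"]),
            "delta_cost": arms[new]["cost_total"] - arms[ref]["cost_total"],
            "delta_cost_discounted": ce.delta_cost,
            "icer": ce.icer,
            "threshold": ce.threshold,
            "category": ce.category,
        },
    }
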