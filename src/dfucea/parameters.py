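"""Parameter model for the diabetic foot ulcer cost-utility analysis.

Holds every input of the weekly-cycle Markov model comparing intra/perilesional
recombinant human epidermal growth factor (rhEGF) as an adjuvant to
conventional wound care against conventional wound care alone, in patients
with Wagner grade 3-4 diabetic foot ulcers:

* per-strategy weekly transition probabilities (wound closure, amputation),
* shared weekly probabilities (disease death, peri-operative amputation death),
* unit costs in USD (drug vials, the weekly wound-care bundle, prostheses,
  amputation surgery, post-closure rehabilitation),
* utility weights for the three alive states,
* economic settings (annual discount rate, time horizon, cost-effectiveness
  threshold as a multiple of GDP per capita, COP/USD exchange rate),
* sensitivity ranges (default +/-20% around each base value).

Also provides the standard decision-model conversions: rate -> probability
(p = 1 - exp(-r*t)), probability rescaling across cycle lengths under a
constant-rate assumption, and per-week compound discount factors.

Parameter files are YAML with the same nesting as :class:`ParameterSet`;
``load_parameters``/``save_parameters`` round-trip them losslessly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

logger = logging.getLogger(__name__)

RHEGF = "rhEGF"
CONVENTIONAL = "conventional"

#: Tolerance used when checking probability invariants.
PROB_TOL = 1e-12


class ParameterError(ValueError):
    """A parameter file or parameter set violates a model invariant.

    Carries ``errors``, a list of ``(field_path, message)`` pairs so callers
    can report every offending field at once.
    """

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"{path}: {msg}" for path, msg in self.errors)
        super().__init__(f"invalid parameters: {lines}")


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def rate_to_probability(rate: float, duration: float = 1.0) -> float:
    """Convert a constant event rate to a probability over ``duration``.

    Uses ``p = 1 - exp(-rate * duration)``, the standard transformation for
    turning trial-reported rates into cycle probabilities.

    Parameters
    ----------
    rate : float
        Events per unit time; must be >= 0.
    duration : float
        Exposure time in the same units; must be >= 0.
    """
    if rate < 0:
        raise ParameterError([("rate", f"must be >= 0, got {rate}")])
    if duration < 0:
        raise ParameterError([("duration", f"must be >= 0, got {duration}")])
    return -math.expm1(-rate * duration)


def probability_to_rate(p: float, duration: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability`: ``r = -ln(1-p)/t``."""
    if not 0 <= p < 1:
        raise ParameterError([("p", f"must be in [0, 1), got {p}")])
    if duration <= 0:
        raise ParameterError([("duration", f"must be > 0, got {duration}")])
    return -math.log1p(-p) / duration


def rescale_probability(p_period: float, n_subperiods: int) -> float:
    """Rescale a probability over a period to one of its equal subperiods.

    Assumes a constant underlying rate, so ``p_sub = 1 - (1-p)^(1/n)``.
    E.g. an annual probability is converted to a weekly one with ``n=52``.
    """
    if not 0 <= p_period < 1:
        raise ParameterError(
            [("p_period", f"must be in [0, 1) (1 implies an infinite rate), got {p_period}")]
        )
    if n_subperiods < 1:
        raise ParameterError([("n_subperiods", f"must be >= 1, got {n_subperiods}")])
    return -math.expm1(math.log1p(-p_period) / n_subperiods)


def weekly_discount_factor(annual_rate: float, week_index):
    """Discount factor ``(1 + r)^(-week/52)`` for a cost or outcome at ``week``.

    Compounds the annual rate smoothly per week. Accepts a scalar or an array
    of week indices and returns the same shape.
    """
    import numpy as np

    if annual_rate < 0:
        raise ParameterError([("annual_rate", f"must be >= 0, got {annual_rate}")])
    week = np.asarray(week_index, dtype=float)
    if np.any(week < 0):
        raise ParameterError([("week_index", "must be >= 0")])
    out = (1.0 + annual_rate) ** (-week / 52.0)
    return float(out) if np.isscalar(week_index) else out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ParameterRange:
    """A sensitivity range around a base value (uniform by default)."""

    base: float
    low: float
    high: float
    distribution: str = "uniform"

    def validate(self, path: str = "range") -> list[tuple[str, str]]:
        errs = []
        if not self.low <= self.base <= self.high:
            errs.append((path, f"requires low <= base <= high, got ({self.low}, {self.base}, {self.high})"))
        if self.distribution not in ("uniform",):
            errs.append((f"{path}.distribution", f"unsupported distribution {self.distribution!r}"))
        return errs


def build_range(
    base: float,
    fraction: float = 0.2,
    cap_at_one: bool = False,
    distribution: str = "uniform",
) -> ParameterRange:
    """Build the +/-``fraction`` sensitivity range around ``base``.

    ``low = base*(1-fraction)``; ``high = base*(1+fraction)``, capped at 1.0
    when ``cap_at_one`` is set (used for probabilities, e.g. the non-closure
    complement 0.9602 whose +20% bound caps at 1.0000).
    """
    if base < 0:
        raise ParameterError([("base", f"must be >= 0, got {base}")])
    if not 0 <= fraction < 1:
        raise ParameterError([("fraction", f"must be in [0, 1), got {fraction}")])
    high = base * (1 + fraction)
    if cap_at_one:
        high = min(high, 1.0)
    return ParameterRange(base=base, low=base * (1 - fraction), high=high,
                          distribution=distribution)


@dataclass
class StrategyParams:
    """Weekly transition probabilities and billing settings for one arm."""

    name: str
    p_closure_week: float
    p_amputation_week: float
    treatment_duration_weeks: int
    weekly_drug_cost: float = 0.0
    #: vials billed per week; when > 0, ``weekly_drug_cost`` is derived as
    #: ``vials_per_week * CostTable.rhegf_vial_with_application``.
    vials_per_week: int = 0
    #: week index before which closure transitions are suppressed
    #: (1 = no suppression; exploratory switch, not part of the base case).
    closure_onset_week: int = 1

    def validate(self, shared: "SharedParams | None" = None,
                 path: str = "strategy") -> list[tuple[str, str]]:
        errs = []
        for fname in ("p_closure_week", "p_amputation_week"):
            v = getattr(self, fname)
            if not 0 <= v <= 1:
                errs.append((f"{path}.{fname}", f"probability must be in [0, 1], got {v}"))
        if self.treatment_duration_weeks < 1:
            errs.append((f"{path}.treatment_duration_weeks", f"must be >= 1, got {self.treatment_duration_weeks}"))
        if self.closure_onset_week < 1:
            errs.append((f"{path}.closure_onset_week", f"must be >= 1, got {self.closure_onset_week}"))
        if self.weekly_drug_cost < 0:
            errs.append((f"{path}.weekly_drug_cost", f"must be >= 0, got {self.weekly_drug_cost}"))
        if shared is not None:
            total = (self.p_closure_week + self.p_amputation_week
                     + shared.p_death_disease_week)
            if total > 1 + PROB_TOL:
                errs.append((
                    f"{path}.p_closure_week",
                    "competing weekly probabilities (closure + amputation + disease death) "
                    f"sum to {total:.6g} > 1",
                ))
        return errs


@dataclass
class SharedParams:
    """Probabilities, mixes and economic settings common to both arms."""

    p_death_disease_week: float = 0.0003
    p_death_amputation_event: float = 0.0029
    annual_discount_rate: float = 0.05
    horizon_weeks: int = 260
    gdp_per_capita_usd: float = 17696.0
    threshold_multiplier: float = 3.0
    cop_per_usd: float = 2951.35
    #: fraction of above-knee amputees fitted with an over-knee prosthesis
    frac_prosthesis_over_knee: float = 1.0
    #: fraction of below-knee amputees fitted with an under-knee prosthesis
    frac_prosthesis_under_knee: float = 0.15
    #: over-knee share of amputations (the level split is not published)
    frac_amputations_over_knee: float = 0.5
    #: whether healed patients remain exposed to disease death
    healed_disease_death: bool = True

    def validate(self, path: str = "shared") -> list[tuple[str, str]]:
        errs = []
        for fname in ("p_death_disease_week", "p_death_amputation_event",
                      "frac_prosthesis_over_knee", "frac_prosthesis_under_knee",
                      "frac_amputations_over_knee"):
            v = getattr(self, fname)
            if not 0 <= v <= 1:
                errs.append((f"{path}.{fname}", f"must be in [0, 1], got {v}"))
        if self.annual_discount_rate < 0:
            errs.append((f"{path}.annual_discount_rate", f"must be >= 0, got {self.annual_discount_rate}"))
        if self.horizon_weeks <= 0:
            errs.append((f"{path}.horizon_weeks", f"must be > 0, got {self.horizon_weeks}"))
        for fname in ("gdp_per_capita_usd", "cop_per_usd"):
            if getattr(self, fname) <= 0:
                errs.append((f"{path}.{fname}", "must be > 0"))
        if self.threshold_multiplier < 0:
            errs.append((f"{path}.threshold_multiplier", "must be >= 0"))
        return errs


#: Printed composition of one week of conventional wound care, USD.
CONVENTIONAL_WEEKLY_COMPONENTS = {
    "wound_care_room": 40.36,
    "wound_care_procedure": 121.33,
    "sodium_chloride_solution": 13.54,
    "gauze": 135.39,
    "elastic_bandages": 26.91,
    "specialist_counselling": 5.51,
}


@dataclass
class CostTable:
    """Unit costs in USD for every billable item in the model."""

    rhegf_vial_with_application: float = 762.87
    conventional_weekly_components: dict[str, float] = field(
        default_factory=lambda: dict(CONVENTIONAL_WEEKLY_COMPONENTS))
    prosthesis_under_knee: float = 1965.22
    prosthesis_over_knee: float = 3049.48
    amputation_procedure: float = 1488.53
    rehabilitation_after_closure: float = 408.80

    @property
    def weekly_conventional_total(self) -> float:
        """Sum of the weekly wound-care bundle components."""
        return sum(self.conventional_weekly_components.values())

    def validate(self, path: str = "costs") -> list[tuple[str, str]]:
        errs = []
        for fname in ("rhegf_vial_with_application", "prosthesis_under_knee",
                      "prosthesis_over_knee", "amputation_procedure",
                      "rehabilitation_after_closure"):
            if getattr(self, fname) < 0:
                errs.append((f"{path}.{fname}", "cost must be >= 0"))
        for k, v in self.conventional_weekly_components.items():
            if v < 0:
                errs.append((f"{path}.conventional_weekly_components.{k}", "cost must be >= 0"))
        return errs


@dataclass
class UtilitySet:
    """Annual utility weights for the alive states.

    The published evaluation does not print its utility values; the defaults
    here are calibrated so the base-case cohort reproduces the published
    per-arm undiscounted QALYs (3.98 rhEGF / 3.32 conventional) with
    ``u_healed`` pinned at 0.95. They are calibrated quantities, not
    elicited ones — see ``outcomes.calibrate_utilities``.
    """

    u_open_ulcer: float = 0.5319
    u_healed: float = 0.95
    u_post_amputation: float = 0.6047

    def validate(self, path: str = "utilities") -> list[tuple[str, str]]:
        errs = []
        for fname in ("u_open_ulcer", "u_healed", "u_post_amputation"):
            v = getattr(self, fname)
            if not 0 <= v <= 1:
                errs.append((f"{path}.{fname}", f"utility must be in [0, 1], got {v}"))
        if self.u_healed < self.u_open_ulcer:
            errs.append((f"{path}.u_healed",
                         "healed state cannot be worse than the open-ulcer state"))
        return errs


@dataclass
class ParameterSet:
    """Everything needed to evaluate one scenario (both strategies)."""

    strategies: dict[str, StrategyParams]
    shared: SharedParams = field(default_factory=SharedParams)
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    #: sensitivity ranges keyed by dotted field path
    ranges: dict[str, ParameterRange] = field(default_factory=dict)

    # -- validation --------------------------------------------------------
    def refresh_derived(self) -> None:
        """Recompute derived fields (vial-based weekly drug costs)."""
        for strat in self.strategies.values():
            if strat.vials_per_week > 0:
                strat.weekly_drug_cost = (
                    strat.vials_per_week * self.costs.rhegf_vial_with_application)

    def validate(self) -> list[tuple[str, str]]:
        self.refresh_derived()
        errs: list[tuple[str, str]] = []
        if not self.strategies:
            errs.append(("strategies", "at least one strategy is required"))
        for name, strat in self.strategies.items():
            errs += strat.validate(self.shared, path=f"strategies.{name}")
        errs += self.shared.validate()
        errs += self.costs.validate()
        errs += self.utilities.validate()
        for rpath, rng in self.ranges.items():
            errs += rng.validate(path=f"ranges.{rpath}")
        return errs

    def raise_if_invalid(self) -> "ParameterSet":
        errs = self.validate()
        if errs:
            raise ParameterError(errs)
        return self

    # -- dotted-path access (used by PSA and the tornado analysis) ---------
    def get_path(self, path: str) -> float:
        obj: Any = self
        for part in path.split("."):
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        return obj

    def set_path(self, path: str, value: float) -> None:
        parts = path.split(".")
        obj: Any = self
        for part in parts[:-1]:
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        if isinstance(obj, dict):
            obj[parts[-1]] = value
        else:
            setattr(obj, parts[-1], value)

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        def strat_d(s: StrategyParams) -> dict:
            return {
                "name": s.name,
                "p_closure_week": s.p_closure_week,
                "p_amputation_week": s.p_amputation_week,
                "treatment_duration_weeks": s.treatment_duration_weeks,
                "weekly_drug_cost": s.weekly_drug_cost,
                "vials_per_week": s.vials_per_week,
                "closure_onset_week": s.closure_onset_week,
            }

        return {
            "strategies": {k: strat_d(v) for k, v in self.strategies.items()},
            "shared": dict(self.shared.__dict__),
            "costs": {
                "rhegf_vial_with_application": self.costs.rhegf_vial_with_application,
                "conventional_weekly_components": dict(self.costs.conventional_weekly_components),
                "prosthesis_under_knee": self.costs.prosthesis_under_knee,
                "prosthesis_over_knee": self.costs.prosthesis_over_knee,
                "amputation_procedure": self.costs.amputation_procedure,
                "rehabilitation_after_closure": self.costs.rehabilitation_after_closure,
            },
            "utilities": dict(self.utilities.__dict__),
            "ranges": {
                k: {"base": r.base, "low": r.low, "high": r.high,
                    "distribution": r.distribution}
                for k, r in self.ranges.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        errs = []
        for key in ("strategies",):
            if key not in d:
                errs.append((key, "missing required section"))
        if errs:
            raise ParameterError(errs)
        strategies = {}
        for name, sd in d["strategies"].items():
            sd = dict(sd)
            sd.setdefault("name", name)
            try:
                strategies[name] = StrategyParams(**sd)
            except TypeError as exc:
                raise ParameterError([(f"strategies.{name}", str(exc))]) from exc
        shared = SharedParams(**d.get("shared", {}))
        cd = d.get("costs", {})
        costs = CostTable(**cd) if cd else CostTable()
        if "utilities" in d:
            utilities = UtilitySet(**d["utilities"])
        else:
            utilities = UtilitySet()
            logger.warning(
                "no utilities in parameter source; using calibrated defaults %s",
                utilities)
        ranges = {k: ParameterRange(**rv) for k, rv in d.get("ranges", {}).items()}
        ps = cls(strategies=strategies, shared=shared, costs=costs,
                 utilities=utilities, ranges=ranges)
        return ps.raise_if_invalid()

    def copy(self) -> "ParameterSet":
        return ParameterSet.from_dict(self.to_dict())


def default_ranges(params: ParameterSet, fraction: float = 0.2) -> dict[str, ParameterRange]:
    """The +/-``fraction`` ranges over every varied model input.

    Covers every transition probability and every unit cost ("modifying all
    the variables included in the model"); utilities are excluded because
    their base values are themselves calibrated. Probabilities are capped at
    1; complements of probabilities are never ranged (they are derived).
    """
    ranges: dict[str, ParameterRange] = {}
    for name in params.strategies:
        for fname in ("p_closure_week", "p_amputation_week"):
            path = f"strategies.{name}.{fname}"
            ranges[path] = build_range(params.get_path(path), fraction, cap_at_one=True)
    for fname in ("p_death_disease_week", "p_death_amputation_event"):
        path = f"shared.{fname}"
        ranges[path] = build_range(params.get_path(path), fraction, cap_at_one=True)
    cost_paths = ["costs.rhegf_vial_with_application", "costs.prosthesis_under_knee",
                  "costs.prosthesis_over_knee", "costs.amputation_procedure",
                  "costs.rehabilitation_after_closure"]
    cost_paths += [f"costs.conventional_weekly_components.{k}"
                   for k in params.costs.conventional_weekly_components]
    for path in cost_paths:
        ranges[path] = build_range(params.get_path(path), fraction, cap_at_one=False)
    return ranges


def load_parameters(source) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from YAML.

    ``source`` may be a path, an open text stream, or an already-parsed
    mapping. Raises :class:`ParameterError` listing every offending field.
    """
    if isinstance(source, Mapping):
        data = source
    elif isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:  # stream
        data = yaml.safe_load(source)
    if not isinstance(data, Mapping):
        raise ParameterError([("<root>", "parameter source is not a mapping")])
    return ParameterSet.from_dict(data)


def save_parameters(params: ParameterSet, path) -> None:
    """Write a :class:`ParameterSet` to YAML (lossless round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
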