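"""Probabilistic and deterministic sensitivity analysis.

The multivariate PSA redraws every ranged parameter independently from its
+/-20% uniform range (the published min/max columns), reruns the whole
pipeline — cohort, costs, QALYs, ICER — and classifies each iteration on the
cost-effectiveness plane. Complement probabilities (e.g. weekly non-closure)
are always derived from the sampled closure probability, never sampled
themselves, so each multinomial row stays coherent; a draw that still
produces an invalid row (competing probabilities summing past 1) is
resampled and counted.

Also provides the cost-effectiveness acceptability curve (CEAC) and a
one-way (tornado) analysis over the same ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import CATEGORIES, classify, compare_strategies, threshold_usd
from .parameters import CONVENTIONAL, RHEGF, ParameterSet, default_ranges

_MAX_RESAMPLE = 1000


@dataclass
class PSAResult:
    """Per-iteration incremental pairs and CE-plane proportions."""

    iterations: pd.DataFrame  # columns: iteration, delta_cost, delta_effect, icer, category
    proportions: dict[str, float]
    n_iterations: int
    seed: int
    threshold: float
    n_resampled: int = 0

    def scatter(self) -> pd.DataFrame:
        """CE-plane points (delta_effect, delta_cost) for plotting/export."""
        return self.iterations[["iteration", "delta_effect", "delta_cost", "category"]]


def sample_parameter_set(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: every ranged parameter uniform on [low, high].

    Returns a validated copy of ``params``; derived quantities (weekly drug
    cost from the vial price, complement probabilities) are recomputed, not
    sampled. Raises ``ParameterError`` if the draw is invalid.
    """
    drawn = params.copy()
    for path, rng_spec in params.ranges.items():
        if rng_spec.low == rng_spec.high:
            value = rng_spec.base
        else:
            value = rng.uniform(rng_spec.low, rng_spec.high)
        drawn.set_path(path, float(value))
    return drawn.raise_if_invalid()


def run_psa(params: ParameterSet, n_iterations: int = 1000, seed: int = 0,
            new: str = RHEGF, ref: str = CONVENTIONAL) -> PSAResult:
    """Monte Carlo sensitivity analysis over the parameter ranges.

    Each iteration samples a full parameter set, reruns both arms end to end
    and records the discounted incremental cost, QALY difference, ICER and
    CE-plane category. Invalid draws are resampled (never silently dropped:
    the count is reported). Reproducible under a fixed seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not params.ranges:
        params = params.copy()
        params.ranges = default_ranges(params)
    rng = np.random.default_rng(seed)
    thr = threshold_usd(params.shared)
    rows = []
    n_resampled = 0
    from .parameters import ParameterError

    for i in range(n_iterations):
        for _attempt in range(_MAX_RESAMPLE):
            try:
                drawn = sample_parameter_set(params, rng)
                break
            except ParameterError:
                n_resampled += 1
        else:
            raise RuntimeError("could not draw a valid parameter set "
                               f"after {_MAX_RESAMPLE} attempts")
        res = compare_strategies(drawn, new=new, ref=ref)
        inc = res["incremental"]
        rows.append((i, inc["delta_cost_discounted"],
                     inc["qalys_gained_discounted"], inc["icer"],
                     inc["category"]))
    df = pd.DataFrame(rows, columns=["iteration", "delta_cost", "delta_effect",
                                     "icer", "category"])
    counts = df["category"].value_counts()
    proportions = {cat: float(counts.get(cat, 0)) / n_iterations
                   for cat in CATEGORIES}
    return PSAResult(iterations=df, proportions=proportions,
                     n_iterations=n_iterations, seed=seed, threshold=thr,
                     n_resampled=n_resampled)


def ceac(psa: PSAResult, threshold_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a threshold grid.

    At each willingness-to-pay value the curve is the fraction of iterations
    with positive net monetary benefit, ``NMB = wtp * delta_effect -
    delta_cost > 0``. Monotone non-decreasing when all iterations gain
    effect; bounded by the fraction with ``delta_cost < 0`` at wtp=0 and the
    fraction with ``delta_effect > 0`` as wtp grows large.
    """
    grid = np.asarray(list(threshold_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    d_eff = psa.iterations["delta_effect"].to_numpy()
    d_cost = psa.iterations["delta_cost"].to_numpy()
    frac = [(wtp * d_eff - d_cost > 0).mean() for wtp in grid]
    return pd.DataFrame({"threshold": grid, "prob_cost_effective": frac})


def tornado(params: ParameterSet, new: str = RHEGF,
            ref: str = CONVENTIONAL) -> pd.DataFrame:
    """One-way sensitivity: each ranged parameter at its bounds, others base.

    Records the discounted ICER at the low and high bound of every range and
    the absolute spread between them, sorted widest first.
    """
    work = params.copy()
    if not work.ranges:
        work.ranges = default_ranges(work)
    rows = []
    for path, rng_spec in work.ranges.items():
        icers = {}
        for bound in ("low", "high"):
            scen = work.copy()
            scen.set_path(path, getattr(rng_spec, bound))
            scen.raise_if_invalid()
            icers[bound] = compare_strategies(scen, new=new, ref=ref)["incremental"]["icer"]
        spread = (abs(icers["high"] - icers["low"])
                  if None not in icers.values() else np.nan)
        rows.append((path, rng_spec.low, rng_spec.high,
                     icers["low"], icers["high"], spread))
    df = pd.DataFrame(rows, columns=["parameter", "low", "high",
                                     "icer_low", "icer_high", "spread"])
    return df.sort_values("spread", ascending=False, ignore_index=True)
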