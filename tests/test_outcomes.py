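"""Cost and QALY accrual, utility calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dfucea
from dfucea import (
    CalibrationError,
    CostTable,
    SharedParams,
    StrategyParams,
    UtilitySet,
    accrue_costs,
    accrue_qalys,
    calibrate_utilities,
    run_cohort,
)

QALY_TARGETS = {"rhEGF": 3.98, "conventional": 3.32}


class TestUnitCostArithmetic:
    def test_weekly_conventional_bundle(self, base_params):
        # the six printed components round-sum one cent below the printed
        # total 343.05, so the bundle is checked to the printed cent
        assert base_params.costs.weekly_conventional_total == pytest.approx(343.05, abs=0.01)

    def test_weekly_rhegf_drug_cost_three_vials(self, base_params):
        assert base_params.strategies["rhEGF"].weekly_drug_cost == pytest.approx(
            3 * 762.87, abs=1e-9)
        assert base_params.strategies["rhEGF"].weekly_drug_cost == pytest.approx(2288.61)


class TestCostAccrual:
    def test_zero_cost_table_accrues_nothing(self, base_params, base_traces):
        zero = CostTable(rhegf_vial_with_application=0.0,
                         conventional_weekly_components={"only": 0.0},
                         prosthesis_under_knee=0.0, prosthesis_over_knee=0.0,
                         amputation_procedure=0.0, rehabilitation_after_closure=0.0)
        strat = base_params.strategies["conventional"]
        cb = accrue_costs(base_traces["conventional"], strat, zero, base_params.shared)
        assert cb.total == 0.0 and cb.discounted_total == 0.0

    def test_total_is_sum_of_categories(self, base_params, base_traces):
        for name, trace in base_traces.items():
            cb = accrue_costs(trace, base_params.strategies[name],
                              base_params.costs, base_params.shared)
            assert cb.total == pytest.approx(
                cb.drugs_and_therapy + cb.amputee_costs
                + cb.procedures_nonclosure + cb.rehabilitation, abs=1e-6)
            assert cb.discounted_total <= cb.total

    def test_drugs_dominate_both_arms(self, base_result):
        # same qualitative pattern as the published 91%/71% cost shares
        for arm in ("rhEGF", "conventional"):
            assert base_result["arms"][arm]["cost_shares"]["drugs_and_therapy"] > 0.60

    def test_unit_cost_monotonicity(self, base_params, base_traces):
        strat = base_params.strategies["conventional"]
        base_cb = accrue_costs(base_traces["conventional"], strat,
                               base_params.costs, base_params.shared)
        dearer = base_params.copy().costs
        dearer.amputation_procedure *= 1.5
        cb = accrue_costs(base_traces["conventional"], strat, dearer,
                          base_params.shared)
        assert cb.amputee_costs > base_cb.amputee_costs
        assert cb.total > base_cb.total
        assert cb.drugs_and_therapy == pytest.approx(base_cb.drugs_and_therapy)

    def test_discount_monotone_in_rate(self, base_params, base_traces):
        strat = base_params.strategies["rhEGF"]
        totals = []
        for rate in (0.0, 0.05, 0.12):
            shared = base_params.copy().shared
            shared.annual_discount_rate = rate
            totals.append(accrue_costs(base_traces["rhEGF"], strat,
                                       base_params.costs, shared).discounted_total)
        assert totals[0] > totals[1] > totals[2]

    def test_rhegf_care_beyond_window_is_nonclosure_procedures(self, base_params, base_traces):
        cb = accrue_costs(base_traces["rhEGF"], base_params.strategies["rhEGF"],
                          base_params.costs, base_params.shared)
        assert cb.procedures_nonclosure > 0  # wound care after the 8-week window
        cb_conv = accrue_costs(base_traces["conventional"],
                               base_params.strategies["conventional"],
                               base_params.costs, base_params.shared)
        assert cb_conv.procedures_nonclosure == 0.0  # billed as therapy while open

    def test_half_cycle_correction_shrinks_weekly_billing(self, base_params, base_traces):
        strat = base_params.strategies["conventional"]
        full = accrue_costs(base_traces["conventional"], strat,
                            base_params.costs, base_params.shared)
        half = accrue_costs(base_traces["conventional"], strat,
                            base_params.costs, base_params.shared, half_cycle=True)
        assert half.drugs_and_therapy < full.drugs_and_therapy
        assert half.amputee_costs == pytest.approx(full.amputee_costs)


class TestQALYAccrual:
    def test_full_health_no_mortality_gives_horizon_years(self):
        shared = SharedParams(p_death_disease_week=0.0, p_death_amputation_event=0.0,
                              annual_discount_rate=0.0)
        trace = run_cohort(StrategyParams(name="x", p_closure_week=0.02,
                                          p_amputation_week=0.01,
                                          treatment_duration_weeks=1), shared)
        q = accrue_qalys(trace, UtilitySet(1.0, 1.0, 1.0), shared)
        assert q.qalys_undiscounted == pytest.approx(5.0, abs=1e-9)
        assert q.qalys_discounted == pytest.approx(5.0, abs=1e-9)

    def test_zero_utilities_give_zero(self, base_params, base_traces):
        q = accrue_qalys(base_traces["rhEGF"], UtilitySet(0.0, 0.0, 0.0),
                         base_params.shared)
        assert q.qalys_undiscounted == 0.0 and q.qalys_discounted == 0.0

    def test_discounted_at_most_undiscounted_at_most_horizon(self, base_params, base_traces):
        for trace in base_traces.values():
            q = accrue_qalys(trace, base_params.utilities, base_params.shared)
            assert 0 <= q.qalys_discounted <= q.qalys_undiscounted <= 5.0

    @given(st.lists(st.floats(0, 1), min_size=6, max_size=6))
    def test_linearity_in_utilities(self, base_params, base_traces, us):
        # QALY(u1 + u2) = QALY(u1) + QALY(u2): accrual is a linear functional
        trace = base_traces["conventional"]
        shared = base_params.shared
        u1 = UtilitySet(us[0], max(us[0], us[1]), us[2])
        u2 = UtilitySet(us[3], max(us[3], us[4]), us[5])
        left = accrue_qalys(trace, UtilitySet(
            u1.u_open_ulcer + u2.u_open_ulcer,
            u1.u_healed + u2.u_healed,
            u1.u_post_amputation + u2.u_post_amputation), shared)
        q1, q2 = accrue_qalys(trace, u1, shared), accrue_qalys(trace, u2, shared)
        assert left.qalys_undiscounted == pytest.approx(
            q1.qalys_undiscounted + q2.qalys_undiscounted, abs=1e-9)
        assert left.qalys_discounted == pytest.approx(
            q1.qalys_discounted + q2.qalys_discounted, abs=1e-9)


class TestCalibration:
    def test_reproduces_published_arm_qalys(self, base_params):
        utilities, info = calibrate_utilities(QALY_TARGETS, base_params, u_healed=0.95)
        ps = base_params.copy()
        ps.utilities = utilities
        for name, target in QALY_TARGETS.items():
            trace = run_cohort(ps.strategies[name], ps.shared)
            q = accrue_qalys(trace, utilities, ps.shared)
            assert q.qalys_undiscounted == pytest.approx(target, abs=1e-3)
        assert "one-parameter family" in info["non_uniqueness"]
        lo, hi = info["feasible_u_healed"]
        assert lo < 0.95 < hi

    def test_default_utilities_are_the_calibrated_ones(self, base_params, base_result):
        # shipped defaults round the calibrated solution to 4 decimals
        utilities, _ = calibrate_utilities(QALY_TARGETS, base_params, u_healed=0.95)
        assert base_params.utilities.u_open_ulcer == pytest.approx(
            utilities.u_open_ulcer, abs=5e-5)
        assert base_params.utilities.u_post_amputation == pytest.approx(
            utilities.u_post_amputation, abs=5e-5)
        assert base_result["arms"]["rhEGF"]["qalys"] == pytest.approx(3.98, abs=1e-3)
        assert base_result["arms"]["conventional"]["qalys"] == pytest.approx(3.32, abs=1e-3)

    def test_perfect_health_targets_solve_to_unit_utilities(self, base_params):
        ps = base_params.copy()
        ps.shared.p_death_disease_week = 0.0
        ps.shared.p_death_amputation_event = 0.0
        utilities, _ = calibrate_utilities({"rhEGF": 5.0, "conventional": 5.0},
                                           ps, u_healed=1.0)
        assert utilities.u_open_ulcer == pytest.approx(1.0, abs=1e-9)
        assert utilities.u_post_amputation == pytest.approx(1.0, abs=1e-9)

    def test_infeasible_targets_raise(self, base_params):
        with pytest.raises(CalibrationError):
            calibrate_utilities({"rhEGF": 10.0, "conventional": 10.0}, base_params)

    def test_unit_healed_utility_is_infeasible_for_published_targets(self, base_params):
        # with u_healed pinned at 1.0 the fitted open-ulcer utility is
        # negative; the error must quote the feasible u_healed interval
        with pytest.raises(CalibrationError, match="feasible u_healed interval"):
            calibrate_utilities(QALY_TARGETS, base_params, u_healed=1.0)
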