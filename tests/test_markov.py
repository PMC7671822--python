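"""Long-term cohort engine: transitions, scheduling, accrual, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scs_cea.decision_tree import run_decision_tree
from scs_cea.markov import (
    build_transition_matrix,
    explant_probability_for_cycle,
    replacement_cycles,
    run_markov,
)
from scs_cea.params import annual_to_cycle_probability, discount_factor
from scs_cea.states import N_STATES, State

from _oracles import microsim_markov


def _unit_state(state: State) -> np.ndarray:
    v = np.zeros(N_STATES)
    v[state] = 1.0
    return v


class TestExplantSchedule:
    def test_year3_rate(self, base_params):
        p = explant_probability_for_cycle(base_params.arms["HF10"], 20)
        assert p == pytest.approx(1 - (1 - 0.032) ** 0.25, abs=1e-12)
        assert p == pytest.approx(0.00810, abs=5e-6)

    def test_year2_rate_low_frequency(self, base_params):
        # cycle 3 starts at month 12
        p = explant_probability_for_cycle(base_params.arms["NRLF"], 3)
        assert p == pytest.approx(1 - (1 - 0.097) ** 0.25, abs=1e-12)
        assert p == pytest.approx(0.02518, abs=1e-5)

    def test_zero_year2_rate(self, base_params):
        params = base_params.with_overrides({"clinical.hf.explant_yr2": 0.0})
        assert explant_probability_for_cycle(params.arms["HF10"], 4) == 0.0

    def test_residual_year1_applies_before_month_12(self, base_params):
        arm = base_params.arms["HF10"]
        for k in (1, 2):
            assert explant_probability_for_cycle(arm, k) == pytest.approx(
                annual_to_cycle_probability(arm.explant_yr1, 0.25)
            )
        with pytest.raises(ValueError):
            explant_probability_for_cycle(arm, 0)


class TestReplacementSchedule:
    @pytest.mark.parametrize(
        "longevity, horizon, expected_years",
        [(4, 15, {4, 8, 12}), (10, 15, {10}), (20, 15, set())],
    )
    def test_replacement_years(self, longevity, horizon, expected_years):
        cycles = replacement_cycles(longevity, horizon)
        years = {0.5 + (k - 1) * 0.25 for k in cycles}
        assert years == expected_years

    def test_longevity_rounded_to_whole_cycle(self):
        assert replacement_cycles(4.1, 15) == replacement_cycles(4.0, 15)
        assert replacement_cycles(0.05, 2) == replacement_cycles(0.25, 2)


class TestTransitionMatrix:
    def test_all_hazards_zero_freezes_states(self, hazard_free_params):
        params = hazard_free_params.with_overrides({"shared.p_reoperation": 0.0})
        M = build_transition_matrix(params.arms["HF10"], params.shared, 10)
        # complication-free and CMM rows are identity; transient
        # with-complication states revert to their complication-free partner
        for s in (State.SCS_OPT_NC, State.SCS_SUBOPT_NC, State.CMM_OPT,
                  State.CMM_NO_RELIEF, State.DEAD):
            assert M[s, s] == 1.0
        assert M[State.SCS_OPT_C, State.SCS_OPT_NC] == 1.0
        assert M[State.SCS_SUBOPT_C, State.SCS_SUBOPT_NC] == 1.0

    def test_mortality_only(self, hazard_free_params):
        params = hazard_free_params.with_overrides(
            {"shared.annual_mortality": 0.0081, "shared.p_reoperation": 0.0}
        )
        M = build_transition_matrix(params.arms["HF10"], params.shared, 10)
        p_d = annual_to_cycle_probability(0.0081, 0.25)
        for s in range(N_STATES - 1):
            assert M[s, State.DEAD] == pytest.approx(p_d, abs=1e-15)
            survivors = 1 - p_d
            if s in (State.SCS_OPT_C, State.SCS_SUBOPT_C):
                # transient complication state reverts when no new event occurs
                assert M[s, s - 1] == pytest.approx(survivors, abs=1e-15)
            else:
                assert M[s, s] == pytest.approx(survivors, abs=1e-15)

    @given(
        mort=st.floats(0, 0.3),
        e1=st.floats(0, 0.5),
        pc=st.floats(0, 0.5),
        reop=st.floats(0, 0.3),
        cycle=st.integers(1, 58),
    )
    @settings(derandomize=True, max_examples=40)
    def test_rows_sum_to_one(self, base_params, mort, e1, pc, reop, cycle):
        params = base_params.with_overrides(
            {
                "shared.annual_mortality": mort,
                "clinical.hf.explant_yr1": e1,
                "clinical.hf.p_complication_late": pc,
                "shared.p_reoperation": reop,
            }
        )
        M = build_transition_matrix(params.arms["HF10"], params.shared, cycle)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert (M >= 0).all()


class TestRunMarkov:
    def test_all_dead_accrues_nothing(self, base_params):
        r = run_markov(
            _unit_state(State.DEAD),
            base_params.arms["HF10"],
            base_params.shared,
            base_params.utilities,
        )
        assert r.total_cost == 0.0
        assert r.total_qalys == 0.0

    def test_hazard_free_undiscounted_annuity(self, hazard_free_params):
        params = hazard_free_params.with_overrides({"shared.discount_rate": 0.0})
        r = run_markov(
            _unit_state(State.SCS_OPT_NC),
            params.arms["HF10"],
            params.shared,
            params.utilities,
        )
        # 14.5 remaining years at utility 0.598
        assert r.total_qalys == pytest.approx(0.598 * 14.5, abs=1e-9)

    def test_hazard_free_discounted_annuity(self, hazard_free_params):
        r = run_markov(
            _unit_state(State.SCS_OPT_NC),
            hazard_free_params.arms["HF10"],
            hazard_free_params.shared,
            hazard_free_params.utilities,
        )
        annuity = sum(
            0.25 * discount_factor(0.5 + 0.25 * k + 0.125, 0.035) for k in range(58)
        )
        assert r.total_qalys == pytest.approx(0.598 * annuity, abs=1e-9)

    def test_mass_conservation_and_monotone_death(self, base_params):
        for arm_name in base_params.arms:
            short = run_decision_tree(
                base_params.arms[arm_name], base_params.shared, base_params.utilities
            )
            r = run_markov(
                short.entering_state,
                base_params.arms[arm_name],
                base_params.shared,
                base_params.utilities,
            )
            occ = r.trace.occupancy_matrix()
            np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
            assert (occ >= -1e-15).all()
            dead = occ[:, State.DEAD]
            assert (np.diff(dead) >= -1e-15).all()
            assert len(r.trace) == 58

    def test_totals_equal_trace_sums(self, base_params):
        short = run_decision_tree(
            base_params.arms["NRLF"], base_params.shared, base_params.utilities
        )
        r = run_markov(
            short.entering_state,
            base_params.arms["NRLF"],
            base_params.shared,
            base_params.utilities,
        )
        assert r.total_cost == pytest.approx(
            sum(c.cycle_cost_discounted for c in r.trace.records), abs=1e-9
        )
        assert r.total_qalys == pytest.approx(
            sum(c.cycle_qalys_discounted for c in r.trace.records), abs=1e-9
        )
        for rec in r.trace.records:
            assert rec.cycle_cost_discounted <= rec.cycle_cost_undiscounted + 1e-12

    def test_discounting_reduces_totals(self, base_params):
        undisc = base_params.with_overrides({"shared.discount_rate": 0.0})
        for p_lo, p_hi in [(base_params, undisc)]:
            short = run_decision_tree(
                p_lo.arms["HF10"], p_lo.shared, p_lo.utilities
            )
            r_disc = run_markov(
                short.entering_state, p_lo.arms["HF10"], p_lo.shared, p_lo.utilities
            )
            r_undisc = run_markov(
                short.entering_state, p_hi.arms["HF10"], p_hi.shared, p_hi.utilities
            )
            assert r_undisc.total_cost > r_disc.total_cost
            assert r_undisc.total_qalys > r_disc.total_qalys

    def test_shorter_longevity_costs_at_least_one_extra_replacement(self, base_params):
        """4-year vs 10-year devices, all else equal: the extra replacements
        must exceed one discounted reimplantation weighted by the implanted
        mass surviving at year 4."""
        p10 = base_params.with_overrides({"arms.NRLF.device_longevity_years": 10})
        short = run_decision_tree(
            base_params.arms["NRLF"], base_params.shared, base_params.utilities
        )
        r4 = run_markov(
            short.entering_state, base_params.arms["NRLF"], base_params.shared,
            base_params.utilities,
        )
        r10 = run_markov(
            short.entering_state, p10.arms["NRLF"], p10.shared, p10.utilities
        )
        # implanted mass at the cycle containing year 4 (cycle 15)
        occ = r4.trace.occupancy_matrix()
        mass_y4 = occ[14, :4].sum()
        floor = (
            base_params.arms["NRLF"].reimplant_cost
            * mass_y4
            * discount_factor(4.125, 0.035)
        )
        assert r4.total_cost - r10.total_cost >= floor

    def test_horizon_must_exceed_tree_block(self, base_params):
        params = base_params.with_overrides({"shared.horizon_years": 0.25})
        with pytest.raises(ValueError):
            run_markov(
                _unit_state(State.SCS_OPT_NC),
                params.arms["HF10"],
                params.shared,
                params.utilities,
            )


@pytest.mark.parametrize("arm_name", ["HF10", "NRLF"])
def test_cohort_matches_patient_level_simulation(base_params, arm_name):
    """The cohort engine equals a 200k-patient microsimulation within 3 SEs."""
    arm = base_params.arms[arm_name]
    short = run_decision_tree(arm, base_params.shared, base_params.utilities)
    cohort = run_markov(
        short.entering_state, arm, base_params.shared, base_params.utilities
    )
    micro = microsim_markov(
        short.entering_state, arm, base_params.shared, base_params.utilities,
        n=200_000, seed=7,
    )
    assert abs(micro["mean_cost"] - cohort.total_cost) <= 3 * micro["se_cost"]
    assert abs(micro["mean_qalys"] - cohort.total_qalys) <= 3 * micro["se_qalys"]
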