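"""Independent per-patient microsimulation oracles.

These re-implement the documented model conventions by sampling individual
patients rather than propagating a cohort vector, and are used to check
that the expectation-based engines agree with the probabilistic process
they claim to represent.  They deliberately avoid the production transition
matrix and branch enumeration.
"""

from __future__ import annotations

import numpy as np

from scs_cea.markov import (
    explant_probability_for_cycle,
    late_complication_cycle_probability,
    replacement_cycles,
)
from scs_cea.params import (
    ArmParameters,
    SharedParameters,
    UtilitySet,
    annual_to_cycle_probability,
    discount_factor,
)
from scs_cea.states import State

# state encoding mirrors scs_cea.states.State
OPT_NC, OPT_C, SUB_NC, SUB_C, CMM_OPT, CMM_NR, DEAD = range(7)


def _utilities(u: UtilitySet) -> np.ndarray:
    return np.array(
        [u.u_opt_nc, u.u_opt_c, u.u_subopt_nc, u.u_subopt_c,
         u.u_opt_nc, u.u_no_relief, 0.0]
    )


def microsim_decision_tree(
    arm: ArmParameters,
    shared: SharedParameters,
    utilities: UtilitySet,
    n: int,
    seed: int,
) -> dict[str, float]:
    """Per-patient simulation of the six-month pathway.

    Returns mean discounted cost and QALYs with their Monte-Carlo standard
    errors, plus the month-6 state distribution.
    """
    rng = np.random.default_rng(seed)
    df = discount_factor(0.25, shared.discount_rate)
    u = _utilities(utilities)
    cmm6 = shared.cost_drug_cmm_6mo + shared.cost_nondrug_cmm_6mo
    scs6 = shared.cost_drug_scs_6mo + shared.cost_nondrug_scs_6mo
    pe0 = 1.0 - (1.0 - arm.explant_yr1) ** 0.5

    success = rng.random(n) < arm.trial_success
    early_explant = success & (rng.random(n) < pe0)
    stay = success & ~early_explant
    on_cmm = ~stay
    cmm_opt = on_cmm & (rng.random(n) < shared.p_optimal_cmm_6mo)
    optimal = stay & (rng.random(n) < arm.p_optimal_6mo)
    comp = stay & (rng.random(n) < arm.p_complication_6mo)

    cost = np.full(n, shared.cost_trial)
    cost[~success] += shared.cost_failed_trial_removal + cmm6
    cost[success] += arm.cost_implant
    cost[early_explant] += shared.cost_explant + cmm6
    cost[stay] += scs6
    cost[stay & comp] += shared.cost_complication

    state = np.empty(n, dtype=int)
    state[on_cmm] = np.where(cmm_opt[on_cmm], CMM_OPT, CMM_NR)
    state[stay] = np.where(
        optimal[stay],
        np.where(comp[stay], OPT_C, OPT_NC),
        np.where(comp[stay], SUB_C, SUB_NC),
    )
    cost = cost * df
    qalys = u[state] * 0.5 * df
    return {
        "mean_cost": float(cost.mean()),
        "se_cost": float(cost.std(ddof=1) / np.sqrt(n)),
        "mean_qalys": float(qalys.mean()),
        "se_qalys": float(qalys.std(ddof=1) / np.sqrt(n)),
        "state_distribution": np.bincount(state, minlength=7) / n,
    }


def microsim_markov(
    initial: np.ndarray,
    arm: ArmParameters,
    shared: SharedParameters,
    utilities: UtilitySet,
    n: int,
    seed: int,
) -> dict[str, float]:
    """Per-patient simulation of the long-term model (month 6 to horizon)."""
    rng = np.random.default_rng(seed)
    h = shared.cycle_length_years
    n_cycles = int(round((shared.horizon_years - 0.5) / h))
    u = _utilities(utilities)
    p_d = annual_to_cycle_probability(shared.annual_mortality, h)
    p_c = late_complication_cycle_probability(arm, h)
    repl = replacement_cycles(arm.device_longevity_years, shared.horizon_years, h)
    scs_cy = (shared.cost_drug_scs_6mo + shared.cost_nondrug_scs_6mo) * h / 0.5
    cmm_cy = (shared.cost_drug_cmm_6mo + shared.cost_nondrug_cmm_6mo) * h / 0.5
    therapy = np.array([scs_cy] * 4 + [cmm_cy] * 2 + [0.0])

    state = rng.choice(7, size=n, p=np.asarray(initial))
    cost = np.zeros(n)
    qalys = np.zeros(n)
    for k in range(1, n_cycles + 1):
        t_mid = 0.5 + (k - 1) * h + h / 2.0
        df = discount_factor(t_mid, shared.discount_rate)
        p_e = explant_probability_for_cycle(arm, k, h)

        start_state = state.copy()
        alive = state != DEAD
        dies = alive & (rng.random(n) < p_d)
        state[dies] = DEAD
        implanted = (state <= SUB_C) & ~dies & alive
        explants = implanted & (rng.random(n) < p_e)
        cost[explants] += shared.cost_explant * df
        to_opt = rng.random(n) < shared.p_optimal_cmm_6mo
        state[explants] = np.where(to_opt[explants], CMM_OPT, CMM_NR)
        retained = implanted & ~explants
        comp = retained & (rng.random(n) < p_c)
        optimal_half = retained & (state <= OPT_C)
        state[retained] = np.where(
            optimal_half[retained],
            np.where(comp[retained], OPT_C, OPT_NC),
            np.where(comp[retained], SUB_C, SUB_NC),
        )
        cost[comp] += shared.cost_complication * df
        # reoperation is drawn for patients who began the cycle without
        # perceived relief (explant entrants wait until the next cycle)
        no_relief = (start_state == CMM_NR) & ~dies
        reop = no_relief & (rng.random(n) < shared.p_reoperation)
        cost[reop] += shared.cost_reoperation * df
        reop_ok = reop & (rng.random(n) < shared.p_optimal_post_reop)
        state[reop_ok] = CMM_OPT

        if k in repl:
            now_implanted = state <= SUB_C
            cost[now_implanted] += arm.reimplant_cost * df
        cost += therapy[state] * df
        qalys += u[state] * h * df

    return {
        "mean_cost": float(cost.mean()),
        "se_cost": float(cost.std(ddof=1) / np.sqrt(n)),
        "mean_qalys": float(qalys.mean()),
        "se_qalys": float(qalys.std(ddof=1) / np.sqrt(n)),
    }
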