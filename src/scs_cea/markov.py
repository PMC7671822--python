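"""Long-term Markov cohort model (month 6 to the end of the horizon).

The cohort enters at month 6 with the state distribution produced by the
decision tree and advances in 3-month cycles.  Implanted patients keep their
month-6 response classification; they leave it only by device explant (to
the CMM pathway), death, or by toggling the transient with-complication
state.  Per cycle:

* all-cause mortality (state-independent, applied first);
* device explant at the annual rate for the current year since implantation
  (residual Year-1 rate over months 6-12, the Year-2 rate over months 12-24,
  the common Year-3+ rate thereafter), converted to a per-cycle probability
  under a constant hazard;
* a non-serious complication with the per-cycle share of the trial's
  beyond-6-month complication probability (observed over months 6-24, an
  18-month window) — a transient one-cycle event that adds the complication
  cost and the with-complication utility for that cycle;
* scheduled device replacement at integer multiples of the (cycle-rounded)
  device longevity, priced at the reimplantation cost for the surviving
  implanted mass.

Explanted patients join CMM alone; on entry they reach optimal relief with
the CMM response probability, the remainder perceiving no relief.  Patients
without perceived relief on CMM may receive spinal surgery (reoperation) in
any cycle — 5% per cycle, of whom 19% achieve optimal relief — which is the
only route out of the no-relief state other than death.  Utilities and
therapy costs accrue on the end-of-cycle occupancy for the cycle length and
are discounted at the cycle midpoint, as are event costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decision_tree import COST_CATEGORIES, utilities_vector
from .params import (
    ArmParameters,
    SharedParameters,
    UtilitySet,
    annual_to_cycle_probability,
    discount_factor,
)
from .states import N_STATES, SCS_STATES, State

__all__ = [
    "CycleRecord",
    "MarkovTrace",
    "LongTermResult",
    "explant_probability_for_cycle",
    "late_complication_cycle_probability",
    "replacement_cycles",
    "build_transition_matrix",
    "run_markov",
]

_MODEL_START_YEARS = 0.5  # the Markov model takes over at month 6

#: the beyond-6-month complication probability covers trial months 6-24
LATE_COMPLICATION_WINDOW_YEARS = 1.5

_SCS = np.array([int(s) for s in SCS_STATES])
_LIVING = np.arange(N_STATES - 1)


@dataclass(frozen=True)
class CycleRecord:
    cycle_index: int
    time_years: float  # cycle start, measured from treatment allocation
    state_vector: np.ndarray
    cycle_cost_undiscounted: float
    cycle_cost_discounted: float
    cycle_qalys_discounted: float
    events: dict[str, float]


@dataclass
class MarkovTrace:
    records: list[CycleRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def occupancy_matrix(self) -> np.ndarray:
        return np.array([r.state_vector for r in self.records])


@dataclass
class LongTermResult:
    total_cost: float
    total_qalys: float
    trace: MarkovTrace | None
    cost_by_category: dict[str, float]
    cost_by_state: np.ndarray
    event_totals: dict[str, float]


def explant_probability_for_cycle(
    arm: ArmParameters, cycle_index: int, cycle_length_years: float = 0.25
) -> float:
    """Per-cycle explant probability for the cycle starting at month 6 + k-1 cycles.

    The annual explant rate in force is chosen by time since implantation:
    the Year-1 rate for cycles within the first year (its first half was
    consumed by the decision tree), the Year-2 rate for the second year, and
    the common Year-3+ rate thereafter.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index starts at 1 (the cycle beginning at month 6)")
    t_start = _MODEL_START_YEARS + (cycle_index - 1) * cycle_length_years
    if t_start < 1.0 - 1e-12:
        annual = arm.explant_yr1
    elif t_start < 2.0 - 1e-12:
        annual = arm.explant_yr2
    else:
        annual = arm.explant_yr3plus
    return annual_to_cycle_probability(annual, cycle_length_years)


def replacement_cycles(
    device_longevity_years: float,
    horizon_years: float,
    cycle_length_years: float = 0.25,
) -> set[int]:
    """Cycle indices (1-based from month 6) holding a scheduled replacement.

    The sampled longevity is rounded to the nearest whole cycle; replacements
    fall at integer multiples of it strictly inside the horizon.  Multiples
    landing before the model start (month 6) are ignored.
    """
    if device_longevity_years <= 0:
        raise ValueError("device_longevity_years must be positive")
    h = cycle_length_years
    longevity = max(h, round(device_longevity_years / h) * h)
    cycles: set[int] = set()
    m = 1
    while True:
        t = m * longevity
        if t >= horizon_years - 1e-9:
            break
        if t >= _MODEL_START_YEARS - 1e-9:
            cycles.add(int(np.floor((t - _MODEL_START_YEARS) / h + 1e-9)) + 1)
        m += 1
    return cycles


def late_complication_cycle_probability(arm: ArmParameters, cycle_length_years: float) -> float:
    """Per-cycle probability of a transient non-serious complication.

    The trial's beyond-6-month complication probability was observed over
    months 6-24 (an 18-month window); it is spread over that window under a
    constant hazard.
    """
    return 1.0 - (1.0 - arm.p_complication_late) ** (
        cycle_length_years / LATE_COMPLICATION_WINDOW_YEARS
    )


def build_transition_matrix(
    arm: ArmParameters, shared: SharedParameters, cycle_index: int
) -> np.ndarray:
    """Row-stochastic transition matrix for one cycle."""
    h = shared.cycle_length_years
    p_d = annual_to_cycle_probability(shared.annual_mortality, h)
    p_e = explant_probability_for_cycle(arm, cycle_index, h)
    p_c = late_complication_cycle_probability(arm, h)
    f_opt = shared.p_optimal_cmm_6mo
    # per-cycle reoperation branch out of the no-relief state
    p_reop_success = shared.p_reoperation * shared.p_optimal_post_reop

    M = np.zeros((N_STATES, N_STATES))
    for opt_pair in ((State.SCS_OPT_NC, State.SCS_OPT_C),
                     (State.SCS_SUBOPT_NC, State.SCS_SUBOPT_C)):
        nc, c = opt_pair
        for s in (nc, c):
            M[s, State.DEAD] = p_d
            M[s, State.CMM_OPT] = (1 - p_d) * p_e * f_opt
            M[s, State.CMM_NO_RELIEF] = (1 - p_d) * p_e * (1 - f_opt)
            rem = (1 - p_d) * (1 - p_e)
            M[s, c] += rem * p_c
            M[s, nc] += rem * (1 - p_c)
    M[State.CMM_OPT, State.DEAD] = p_d
    M[State.CMM_OPT, State.CMM_OPT] = 1 - p_d
    M[State.CMM_NO_RELIEF, State.DEAD] = p_d
    M[State.CMM_NO_RELIEF, State.CMM_OPT] = (1 - p_d) * p_reop_success
    M[State.CMM_NO_RELIEF, State.CMM_NO_RELIEF] = (1 - p_d) * (1 - p_reop_success)
    M[State.DEAD, State.DEAD] = 1.0

    rows = M.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-12):
        raise RuntimeError(f"transition matrix rows do not sum to 1: {rows}")
    return M


def run_markov(
    initial: np.ndarray,
    arm: ArmParameters,
    shared: SharedParameters,
    utilities: UtilitySet,
    collect_trace: bool = True,
) -> LongTermResult:
    """Propagate the cohort from month 6 to the horizon and accrue outcomes."""
    if shared.horizon_years <= _MODEL_START_YEARS:
        raise ValueError("horizon_years must exceed the 6-month decision-tree block")
    v = np.asarray(initial, dtype=float)
    if v.shape != (N_STATES,) or np.any(v < -1e-15) or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("initial must be a valid state vector summing to 1")

    h = shared.cycle_length_years
    n_cycles = int(round((shared.horizon_years - _MODEL_START_YEARS) / h))
    rate = shared.discount_rate
    u = utilities_vector(utilities)
    p_d = annual_to_cycle_probability(shared.annual_mortality, h)
    p_c = late_complication_cycle_probability(arm, h)
    repl_cycles = replacement_cycles(arm.device_longevity_years, shared.horizon_years, h)

    scale = h / 0.5  # 6-month therapy costs prorated to one cycle
    scs_drug = shared.cost_drug_scs_6mo * scale
    scs_nondrug = shared.cost_nondrug_scs_6mo * scale
    cmm_drug = shared.cost_drug_cmm_6mo * scale
    cmm_nondrug = shared.cost_nondrug_cmm_6mo * scale

    v = v.copy()
    cost_by_category = {cat: 0.0 for cat in COST_CATEGORIES}
    cost_by_state = np.zeros(N_STATES)
    event_totals = {k: 0.0 for k in
                    ("explants", "replacements", "complications", "reoperations", "deaths")}
    total_cost = 0.0
    total_qalys = 0.0
    records: list[CycleRecord] = []

    matrix_cache: dict[float, np.ndarray] = {}
    for k in range(1, n_cycles + 1):
        t_start = _MODEL_START_YEARS + (k - 1) * h
        t_mid = t_start + h / 2.0
        df = discount_factor(t_mid, rate)

        p_e = explant_probability_for_cycle(arm, k, h)
        M = matrix_cache.get(p_e)
        if M is None:
            M = build_transition_matrix(arm, shared, k)
            matrix_cache[p_e] = M

        living = v[_LIVING].sum()
        scs_mass = v[_SCS].sum()
        deaths = living * p_d
        explants_by_state = v[_SCS] * (1 - p_d) * p_e
        explants = explants_by_state.sum()
        complications = scs_mass * (1 - p_d) * (1 - p_e) * p_c
        reops = v[State.CMM_NO_RELIEF] * (1 - p_d) * shared.p_reoperation

        v_new = v @ M

        scs_end = v_new[_SCS].sum()
        cmm_end = v_new[State.CMM_OPT] + v_new[State.CMM_NO_RELIEF]
        replacements = scs_end if k in repl_cycles else 0.0

        reop_cost_cycle = reops * shared.cost_reoperation
        cat = {
            "therapy_drug": scs_end * scs_drug + cmm_end * cmm_drug,
            "therapy_nondrug": scs_end * scs_nondrug + cmm_end * cmm_nondrug,
            "explants": explants * shared.cost_explant,
            "complications": complications * shared.cost_complication,
            "reoperations": reop_cost_cycle,
            "device_replacement": replacements * arm.reimplant_cost,
        }
        cycle_cost = sum(cat.values())
        cycle_cost_disc = cycle_cost * df
        cycle_qalys_disc = float(u @ v_new) * h * df

        for key, val in cat.items():
            cost_by_category[key] += val * df
        # per-state attribution: therapy to the occupied state, explant cost
        # to the implanted state it left, complication cost to the transient
        # with-complication states, replacement pro-rata over implanted mass
        cost_by_state[_SCS] += v_new[_SCS] * (scs_drug + scs_nondrug) * df
        for s in (State.CMM_OPT, State.CMM_NO_RELIEF):
            cost_by_state[s] += v_new[s] * (cmm_drug + cmm_nondrug) * df
        cost_by_state[_SCS] += explants_by_state * shared.cost_explant * df
        if scs_mass > 0:
            comp_w = v[_SCS] / scs_mass
            cost_by_state[_SCS] += comp_w * complications * shared.cost_complication * df
        cost_by_state[State.CMM_NO_RELIEF] += reop_cost_cycle * df
        if replacements > 0 and scs_end > 0:
            cost_by_state[_SCS] += (
                v_new[_SCS] / scs_end * replacements * arm.reimplant_cost * df
            )

        event_totals["explants"] += explants
        event_totals["replacements"] += replacements
        event_totals["complications"] += complications
        event_totals["reoperations"] += reops
        event_totals["deaths"] += deaths
        total_cost += cycle_cost_disc
        total_qalys += cycle_qalys_disc

        if collect_trace:
            records.append(
                CycleRecord(
                    cycle_index=k,
                    time_years=t_start,
                    state_vector=v_new.copy(),
                    cycle_cost_undiscounted=cycle_cost,
                    cycle_cost_discounted=cycle_cost_disc,
                    cycle_qalys_discounted=cycle_qalys_disc,
                    events={
                        "explants": explants,
                        "replacements": replacements,
                        "complications": complications,
                        "reoperations": reops,
                        "deaths": deaths,
                    },
                )
            )
        v = v_new

    return LongTermResult(
        total_cost=total_cost,
        total_qalys=total_qalys,
        trace=MarkovTrace(records) if collect_trace else None,
        cost_by_category=cost_by_category,
        cost_by_state=cost_by_state,
        event_totals=event_totals,
    )
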