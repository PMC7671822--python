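"""First-six-months decision tree.

Patients allocated to SCS undergo a screening trial with an external
stimulator.  Successes receive a permanent implant; failures have the trial
electrode removed and revert to conventional medical management (CMM) alone.
Implanted patients may have the device explanted within the first six months
(the first half-year share of the Year-1 explant rate, constant-hazard
split); those who keep the device are classified at month 6 as having
optimal (>=50% leg-pain VAS reduction) or sub-optimal pain relief, each with
or without a non-serious complication (response and complication treated as
independent).  CMM-alone patients reach optimal relief with the CMM response
probability; the remainder perceive no relief.

Every branch accrues the trial cost, six months of the applicable drug and
non-drug therapy cost, branch-specific event costs, and half a year of
state utility; the whole block is discounted at the mid-period factor
(0.25 years).  Mortality is not applied during the tree (six-month all-cause
mortality ~0.4% is negligible and the pathway has no death branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ArmParameters, SharedParameters, UtilitySet, discount_factor
from .states import N_STATES, State

__all__ = ["Branch", "ShortTermResult", "enumerate_branches", "run_decision_tree"]

COST_CATEGORIES = (
    "trial",
    "device_implant",
    "device_replacement",
    "therapy_drug",
    "therapy_nondrug",
    "complications",
    "explants",
    "reoperations",
)


@dataclass(frozen=True)
class Branch:
    """One leaf of the enumerated tree: probability mass, end state, costs."""

    label: str
    probability: float
    end_state: State
    cost_by_category: dict[str, float]

    @property
    def cost(self) -> float:
        return sum(self.cost_by_category.values())


@dataclass
class ShortTermResult:
    """Six-month outcomes for one arm, discounted at the mid-period factor."""

    arm: str
    cost_6mo: float
    qalys_6mo: float
    entering_state: np.ndarray  # month-6 occupancy over the 7 states
    fraction_implanted: float  # received a permanent implant (trial successes)
    fraction_cmm: float  # never implanted (trial failures)
    event_counts: dict[str, float]
    cost_by_category: dict[str, float] = field(default_factory=dict)
    cost_by_state: np.ndarray | None = None


def enumerate_branches(
    arm: ArmParameters, shared: SharedParameters
) -> list[Branch]:
    """Enumerate the tree's leaves with their probabilities and cost makeup."""
    ts = arm.trial_success
    # half-year share of the Year-1 explant rate, constant hazard
    pe0 = 1.0 - (1.0 - arm.explant_yr1) ** 0.5
    p_opt = arm.p_optimal_6mo
    p_comp = arm.p_complication_6mo
    p_cmm = shared.p_optimal_cmm_6mo

    cmm_therapy = {
        "therapy_drug": shared.cost_drug_cmm_6mo,
        "therapy_nondrug": shared.cost_nondrug_cmm_6mo,
    }
    scs_therapy = {
        "therapy_drug": shared.cost_drug_scs_6mo,
        "therapy_nondrug": shared.cost_nondrug_scs_6mo,
    }

    branches: list[Branch] = []

    def add(label: str, prob: float, state: State, **costs: float) -> None:
        branches.append(
            Branch(label, prob, state, {"trial": shared.cost_trial, **costs})
        )

    # (a) failed screening trial -> electrode removal, CMM alone
    fail_costs = {"explants": shared.cost_failed_trial_removal, **cmm_therapy}
    add("fail/cmm_opt", (1 - ts) * p_cmm, State.CMM_OPT, **fail_costs)
    add("fail/cmm_nr", (1 - ts) * (1 - p_cmm), State.CMM_NO_RELIEF, **fail_costs)

    # (b) implanted, device explanted within months 0-6 -> CMM pathway
    ex_costs = {
        "device_implant": arm.cost_implant,
        "explants": shared.cost_explant,
        **cmm_therapy,
    }
    add("explant/cmm_opt", ts * pe0 * p_cmm, State.CMM_OPT, **ex_costs)
    add("explant/cmm_nr", ts * pe0 * (1 - p_cmm), State.CMM_NO_RELIEF, **ex_costs)

    # (c) implanted and retained: response x complication split
    stay = ts * (1 - pe0)
    base = {"device_implant": arm.cost_implant, **scs_therapy}
    comp = {**base, "complications": shared.cost_complication}
    add("scs/opt_nc", stay * p_opt * (1 - p_comp), State.SCS_OPT_NC, **base)
    add("scs/opt_c", stay * p_opt * p_comp, State.SCS_OPT_C, **comp)
    add("scs/subopt_nc", stay * (1 - p_opt) * (1 - p_comp), State.SCS_SUBOPT_NC, **base)
    add("scs/subopt_c", stay * (1 - p_opt) * p_comp, State.SCS_SUBOPT_C, **comp)

    return branches


def run_decision_tree(
    arm: ArmParameters, shared: SharedParameters, utilities: UtilitySet
) -> ShortTermResult:
    """Evaluate the six-month tree in expectation over the enumerated leaves."""
    branches = enumerate_branches(arm, shared)
    df = discount_factor(0.25, shared.discount_rate)
    u = utilities_vector(utilities)

    occupancy = np.zeros(N_STATES)
    cost_by_category = {cat: 0.0 for cat in COST_CATEGORIES}
    cost_by_state = np.zeros(N_STATES)
    qalys = 0.0
    for b in branches:
        occupancy[b.end_state] += b.probability
        for cat, c in b.cost_by_category.items():
            cost_by_category[cat] += b.probability * c * df
        cost_by_state[b.end_state] += b.probability * b.cost * df
        qalys += b.probability * u[b.end_state] * 0.5 * df

    ts = arm.trial_success
    pe0 = 1.0 - (1.0 - arm.explant_yr1) ** 0.5
    events = {
        "trial_failures": 1.0 - ts,
        "explants": ts * pe0,
        "complications": ts * (1 - pe0) * arm.p_complication_6mo,
    }
    return ShortTermResult(
        arm=arm.arm,
        cost_6mo=float(cost_by_state.sum()),
        qalys_6mo=qalys,
        entering_state=occupancy,
        fraction_implanted=ts,
        fraction_cmm=1.0 - ts,
        event_counts=events,
        cost_by_category=cost_by_category,
        cost_by_state=cost_by_state,
    )


def utilities_vector(utilities: UtilitySet) -> np.ndarray:
    """Per-state utility vector; CMM responders use the optimal-relief utility."""
    u = np.zeros(N_STATES)
    u[State.SCS_OPT_NC] = utilities.u_opt_nc
    u[State.SCS_OPT_C] = utilities.u_opt_c
    u[State.SCS_SUBOPT_NC] = utilities.u_subopt_nc
    u[State.SCS_SUBOPT_C] = utilities.u_subopt_c
    u[State.CMM_OPT] = utilities.u_opt_nc
    u[State.CMM_NO_RELIEF] = utilities.u_no_relief
    u[State.DEAD] = 0.0
    return u
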