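"""Per-arm evaluation and incremental cost-effectiveness comparisons.

Totals per arm are the six-month decision-tree block plus the Markov block,
both discounted at 3.5% per annum in the base case.  Comparisons report the
incremental cost and QALYs of a comparator against the reference arm and
classify dominance: a strategy with higher costs and fewer QALYs than the
reference is dominated (no ICER is reported); when the signs agree the ICER
is the cost difference per QALY difference.  The net-monetary-benefit (NMB)
difference at the willingness-to-pay threshold is reported alongside
(NMB = WTP * QALYs - cost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .decision_tree import COST_CATEGORIES, run_decision_tree
from .markov import LongTermResult, run_markov
from .params import ParameterSet
from .states import N_STATES, STATE_LABELS, State

__all__ = ["ArmResult", "Comparison", "Dominance", "evaluate_arm", "evaluate_all", "compare"]


class Dominance(str, Enum):
    REFERENCE_DOMINANT = "reference_dominant"
    COMPARATOR_DOMINANT = "comparator_dominant"
    ICER_REPORTED = "icer_reported"


@dataclass
class ArmResult:
    """Discounted lifetime (15-year) totals and cost breakdowns for one arm."""

    arm: str
    total_cost: float
    total_qalys: float
    cost_by_category: dict[str, float]
    cost_by_state: dict[str, float]
    short_term_cost: float
    short_term_qalys: float
    long_term: LongTermResult | None = None


@dataclass
class Comparison:
    """Comparator-minus-reference increments with dominance classification."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    icer: float | None
    classification: Dominance
    nmb_difference: float  # reference NMB minus comparator NMB at the WTP
    tie: bool = False


def evaluate_arm(
    params: ParameterSet, arm: str, collect_trace: bool = False
) -> ArmResult:
    """Run decision tree + Markov model for one arm and combine the blocks."""
    if arm not in params.arms:
        raise ValueError(f"unknown arm {arm!r}; expected one of {sorted(params.arms)}")
    arm_params = params.arms[arm]
    short = run_decision_tree(arm_params, params.shared, params.utilities)
    long = run_markov(
        short.entering_state, arm_params, params.shared, params.utilities,
        collect_trace=collect_trace,
    )
    categories = {
        cat: short.cost_by_category.get(cat, 0.0) + long.cost_by_category.get(cat, 0.0)
        for cat in COST_CATEGORIES
    }
    by_state = np.asarray(short.cost_by_state) + long.cost_by_state
    return ArmResult(
        arm=arm,
        total_cost=short.cost_6mo + long.total_cost,
        total_qalys=short.qalys_6mo + long.total_qalys,
        cost_by_category=categories,
        cost_by_state={STATE_LABELS[State(i)]: float(by_state[i]) for i in range(N_STATES)},
        short_term_cost=short.cost_6mo,
        short_term_qalys=short.qalys_6mo,
        long_term=long if collect_trace else None,
    )


def evaluate_all(params: ParameterSet, collect_trace: bool = False) -> dict[str, ArmResult]:
    return {arm: evaluate_arm(params, arm, collect_trace) for arm in params.arms}


def compare(reference: ArmResult, comparator: ArmResult, wtp: float) -> Comparison:
    """Incremental comparison of ``comparator`` against ``reference``."""
    d_cost = comparator.total_cost - reference.total_cost
    d_qalys = comparator.total_qalys - reference.total_qalys
    nmb_diff = (wtp * reference.total_qalys - reference.total_cost) - (
        wtp * comparator.total_qalys - comparator.total_cost
    )

    tie = d_cost == 0.0 or d_qalys == 0.0
    if d_qalys == 0.0:
        if d_cost == 0.0:
            icer: float | None = 0.0
            cls = Dominance.ICER_REPORTED
        else:
            icer = math.inf if d_cost > 0 else -math.inf
            cls = (
                Dominance.REFERENCE_DOMINANT if d_cost > 0
                else Dominance.COMPARATOR_DOMINANT
            )
    elif d_cost > 0 and d_qalys < 0:
        icer, cls = None, Dominance.REFERENCE_DOMINANT
    elif d_cost < 0 and d_qalys > 0:
        icer, cls = None, Dominance.COMPARATOR_DOMINANT
    else:
        icer, cls = d_cost / d_qalys, Dominance.ICER_REPORTED

    return Comparison(
        reference=reference.arm,
        comparator=comparator.arm,
        delta_cost=d_cost,
        delta_qalys=d_qalys,
        icer=icer,
        classification=cls,
        nmb_difference=nmb_diff,
        tie=tie,
    )
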