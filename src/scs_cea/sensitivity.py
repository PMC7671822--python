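"""Deterministic sensitivity analyses: tornado, threshold, and scenarios.

One-way analysis sets each parameter in turn to its lower and upper 95%
confidence limit with all other parameters at base case, and records the
movement of the chosen outcome (incremental cost, or the incremental
net-monetary-benefit representation for the cost-utility analysis, which
avoids ICER sign pathologies under dominance).  Threshold analysis bisects a
single parameter to the value at which the reference arm becomes
cost-neutral (incremental cost zero) or its ICER equals the willingness-to-
pay threshold (incremental NMB zero).  Scenario analysis re-runs the full
deterministic model under a named set of parameter overrides; the packaged
scenarios cover equal explant rates for all devices (3.2%/year), equal
non-serious complication rates, the alternative system-costing (equal-price)
scenario, and time-horizon variation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .cea import ArmResult, Comparison, compare, evaluate_all
from .params import ParameterSet

__all__ = [
    "TornadoEntry",
    "ThresholdResult",
    "Scenario",
    "ScenarioResult",
    "owsa",
    "threshold_search",
    "run_scenario",
    "packaged_scenario",
    "PACKAGED_SCENARIOS",
]

logger = logging.getLogger(__name__)


@dataclass
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def span(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


@dataclass
class ThresholdResult:
    parameter: str
    objective: str  # "cost_neutral" | "icer_equals_wtp"
    threshold_value: float | None
    achieved_objective_residual: float | None
    bracketed: bool
    bracket: tuple[float, float]


@dataclass
class Scenario:
    """A named set of parameter overrides (dotted path -> value)."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)


@dataclass
class ScenarioResult:
    scenario: Scenario
    arm_results: dict[str, ArmResult]
    comparisons: dict[str, Comparison]


def _outcome(
    params: ParameterSet, outcome: str, comparator: str, reference: str, wtp: float
) -> float:
    res = evaluate_all(params)
    cmp_ = compare(res[reference], res[comparator], wtp)
    if outcome == "delta_cost":
        return cmp_.delta_cost
    if outcome == "icer_or_nmb":
        # incremental NMB of the reference over the comparator; positive
        # favours the reference, zero marks ICER == WTP
        return cmp_.nmb_difference
    raise ValueError(f"unknown outcome {outcome!r}")


def owsa(
    params: ParameterSet,
    outcome: str = "delta_cost",
    comparator: str = "NRLF",
    reference: str = "HF10",
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis over every parameter with CI bounds.

    Each parameter is set to its lower then upper 95% confidence limit with
    all others at base case.  Entries are sorted by descending span (the
    first 10 are the tornado diagram's rows; all parameters are tested).
    Parameters without bounds are skipped with a logged warning.
    """
    wtp = params.shared.wtp_per_qaly if wtp is None else wtp
    entries: list[TornadoEntry] = []
    for name, spec in params.specs.items():
        if not spec.is_sampled:
            if spec.family != "fixed":
                logger.warning("parameter %s has no CI bounds; skipped", name)
            continue
        lo = _outcome(params.with_overrides({name: spec.ci_low}), outcome,
                      comparator, reference, wtp)
        hi = _outcome(params.with_overrides({name: spec.ci_high}), outcome,
                      comparator, reference, wtp)
        entries.append(TornadoEntry(name, spec.ci_low, spec.ci_high, lo, hi))
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def threshold_search(
    params: ParameterSet,
    parameter: str,
    objective: str = "cost_neutral",
    comparator: str = "NRLF",
    reference: str = "HF10",
    tolerance: float = 1.0,
    bracket: tuple[float, float] | None = None,
    wtp: float | None = None,
    max_iter: int = 200,
) -> ThresholdResult:
    """Bisect one parameter to the value meeting the stated objective.

    ``cost_neutral`` seeks incremental cost zero; ``icer_equals_wtp`` seeks
    incremental NMB zero at the willingness-to-pay threshold.  The default
    bracket is the parameter's 95% CI.  If the objective does not change
    sign over the bracket, a non-bracketed result is returned (not an
    exception).  The residual tolerance defaults to £1.
    """
    if objective not in ("cost_neutral", "icer_equals_wtp"):
        raise ValueError(f"unknown objective {objective!r}")
    outcome = "delta_cost" if objective == "cost_neutral" else "icer_or_nmb"
    wtp = params.shared.wtp_per_qaly if wtp is None else wtp
    if bracket is None:
        spec = params.specs.get(parameter)
        if spec is None:
            raise ValueError(f"unknown parameter {parameter!r}")
        bracket = (spec.ci_low, spec.ci_high)
    lo, hi = bracket

    def f(x: float) -> float:
        return _outcome(params.with_overrides({parameter: x}), outcome,
                        comparator, reference, wtp)

    base = params.base_value(parameter)
    if lo <= base <= hi:
        r = f(base)
        if abs(r) <= tolerance:
            return ThresholdResult(parameter, objective, base, r, True, bracket)

    f_lo, f_hi = f(lo), f(hi)
    for x, r in ((lo, f_lo), (hi, f_hi)):
        if abs(r) <= tolerance:
            return ThresholdResult(parameter, objective, x, r, True, bracket)
    if f_lo * f_hi > 0:
        return ThresholdResult(parameter, objective, None, None, False, bracket)

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = f(mid)
        if abs(r) <= tolerance:
            return ThresholdResult(parameter, objective, mid, r, True, bracket)
        if (r > 0) == (f_lo > 0):
            lo, f_lo = mid, r
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return ThresholdResult(parameter, objective, mid, f(mid), True, bracket)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

_EXPLANT_PATHS = [
    f"clinical.{grp}.{fld}"
    for grp in ("hf", "lf")
    for fld in ("explant_yr1", "explant_yr2", "explant_yr3plus")
]


def _equal_explant() -> Scenario:
    return Scenario("equal_explant_3.2", {p: 0.032 for p in _EXPLANT_PATHS})


def _equal_complications() -> Scenario:
    # all device types at the (higher) low-frequency complication rates,
    # conservative against the high-frequency arm
    return Scenario(
        "equal_complications",
        {
            "clinical.hf.p_complication_6mo": 0.358,
            "clinical.hf.p_complication_late": 0.128,
        },
    )


def _alternative_system_costs() -> Scenario:
    return Scenario(
        "alternative_system_costs",
        {
            "arms.HF10.cost_implant": 16648,
            "arms.NRLF.cost_implant": 11281,
            "arms.RLF.cost_implant": 16648,
            "arms.HF10.cost_reimplant": 14201,
            "arms.NRLF.cost_reimplant": 10499,
            "arms.RLF.cost_reimplant": 14201,
        },
    )


PACKAGED_SCENARIOS = {
    "equal_explant_3.2": _equal_explant,
    "equal_complications": _equal_complications,
    "alternative_system_costs": _alternative_system_costs,
    "horizon_<N>y": None,  # pattern, handled by packaged_scenario()
}

_HORIZON_RE = re.compile(r"^horizon_(\d+)y$")


def packaged_scenario(name: str) -> Scenario:
    """Look up a packaged scenario by name (``horizon_<N>y`` is a pattern)."""
    m = _HORIZON_RE.match(name)
    if m:
        return Scenario(name, {"shared.horizon_years": float(m.group(1))})
    factory = PACKAGED_SCENARIOS.get(name)
    if factory is None:
        available = sorted(PACKAGED_SCENARIOS)
        raise ValueError(f"unknown scenario {name!r}; available: {available}")
    return factory()


def run_scenario(
    params: ParameterSet, scenario: Scenario | str, wtp: float | None = None
) -> ScenarioResult:
    """Full deterministic analysis under a scenario's parameter overrides."""
    if isinstance(scenario, str):
        scenario = packaged_scenario(scenario)
    overridden = params.with_overrides(scenario.overrides)
    wtp = overridden.shared.wtp_per_qaly if wtp is None else wtp
    results = evaluate_all(overridden)
    ref = results["HF10"]
    comparisons = {
        arm: compare(ref, res, wtp) for arm, res in results.items() if arm != "HF10"
    }
    return ScenarioResult(scenario, results, comparisons)
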