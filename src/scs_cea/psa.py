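"""Probabilistic sensitivity analysis.

All parameters are varied simultaneously: clinical probabilities and
utilities are drawn from beta distributions and costs and device longevity
from gamma distributions, each moment-matched to the parameter's 95% CI
(see :mod:`scs_cea.params`).  The clinical parameters the two low-frequency
arms share are drawn once per iteration and reused for both, while
device-specific implant costs and longevities are drawn separately; this
mirrors how the parameters are pooled in the source trial analysis.  Each
of the (default 5000) iterations runs the full decision tree + Markov model
for all three arms; results are summarised as the probability that the
10 kHz arm is cost-saving, the mean cost difference with a normal-
approximation 95% CI (a percentile interval is reported alongside), and
cost-effectiveness acceptability curves (CEACs) over a willingness-to-pay
grid, where a draw counts as cost-effective when the 10 kHz arm has the
higher net monetary benefit.

Randomness is reproducible by construction: every (seed, draw, parameter)
triple keys its own PRNG substream, so results do not depend on evaluation
order and are bit-identical across runs with the same seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .cea import evaluate_arm
from .params import (
    DistributionSpec,
    FitError,
    ParameterSet,
    fit_beta_from_ci,
    fit_gamma_from_ci,
)

__all__ = ["PSAResult", "sample_parameter_set", "sample_value", "run_psa", "ceac"]

DEFAULT_WTP_GRID = tuple(float(w) for w in range(0, 50001, 2500))


@dataclass
class ComparisonSummary:
    comparator: str
    prob_cost_saving: float
    mean_delta_cost: float
    mean_delta_cost_ci: tuple[float, float]  # normal approximation
    mean_delta_cost_percentile_ci: tuple[float, float]
    mean_delta_qalys: float
    ceac: list[tuple[float, float]]


@dataclass
class PSAResult:
    n_draws: int
    seed: int
    comparisons: dict[str, ComparisonSummary]
    costs: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    qalys: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def delta_cost(self, comparator: str, reference: str = "HF10") -> np.ndarray:
        return self.costs[comparator] - self.costs[reference]

    def delta_qalys(self, comparator: str, reference: str = "HF10") -> np.ndarray:
        return self.qalys[comparator] - self.qalys[reference]


def _substream(seed: int, draw_index: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        [int(seed), int(draw_index), zlib.crc32(name.encode("utf-8"))]
    )


def _stream_key(spec: DistributionSpec) -> str:
    """Substream key identifying the underlying uncertain quantity.

    Parameters printed as the same assumption — identical value, interval and
    family (e.g. the common Year-3+ explant rate, or the 10-year device
    longevity assumed for both the 10 kHz and rechargeable low-frequency
    devices) — are one uncertain quantity and share one draw.  Gamma-sampled
    quantities are keyed on their *relative* interval, so cost intervals
    constructed by a common proportional difference (the implant-cost CIs)
    share their relative deviate; the marginal distribution is unchanged
    because the gamma family is closed under scaling.
    """
    if spec.family == "gamma":
        lo, hi = _relative_interval(spec)
        return f"gamma-rel|{lo:.3f}|{hi:.3f}"
    return f"{spec.family}|{spec.base_value:.12g}|{spec.ci_low:.12g}|{spec.ci_high:.12g}"


def _relative_interval(spec: DistributionSpec) -> tuple[float, float]:
    # quantised at 0.1% — the source values are printed to the pound, so
    # proportionally constructed intervals match exactly after rounding
    return (
        round(spec.ci_low / spec.base_value, 3),
        round(spec.ci_high / spec.base_value, 3),
    )


def sample_value(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from a parameter's fitted distribution.

    Beta parameters whose CI is too wide to moment-match fall back to a
    uniform draw on the CI.
    """
    if not spec.is_sampled:
        return spec.base_value
    if spec.family == "beta":
        try:
            a, b = fit_beta_from_ci(spec.base_value, spec.ci_low, spec.ci_high)
        except FitError:
            return float(rng.uniform(spec.ci_low, spec.ci_high))
        return float(rng.beta(a, b))
    # draw the relative deviate (mean 1) and scale by the base value, so
    # parameters sharing a relative-interval substream stay proportional
    shape, scale = fit_gamma_from_ci(1.0, *_relative_interval(spec))
    return float(spec.base_value * rng.gamma(shape) * scale)


def sample_parameter_set(
    params: ParameterSet, rng_seed: int, draw_index: int
) -> ParameterSet:
    """Independently sample every non-fixed parameter of the configuration.

    Deterministic given ``(rng_seed, draw_index)``.  Parameters shared
    between the low-frequency arms appear once in the configuration and are
    therefore drawn once.  Sampled device longevity is floored at one cycle
    so a replacement can be scheduled.
    """
    overrides: dict[str, float] = {}
    for name, spec in params.specs.items():
        if not spec.is_sampled:
            continue
        value = sample_value(spec, _substream(rng_seed, draw_index, _stream_key(spec)))
        if name.endswith("device_longevity_years"):
            value = max(value, params.shared.cycle_length_years)
        overrides[name] = value
    return params.with_overrides(overrides)


def ceac(
    delta_cost: np.ndarray, delta_qalys: np.ndarray, wtp_grid: tuple[float, ...]
) -> list[tuple[float, float]]:
    """Probability the reference arm has the higher NMB at each WTP point.

    Deltas are comparator minus reference; the reference wins a draw when
    ``delta_cost - wtp * delta_qalys > 0``.  At WTP 0 this reduces to the
    probability of being cost-saving.
    """
    if delta_cost.size == 0:
        raise ValueError("CEAC requires at least one PSA draw")
    if any(w < 0 for w in wtp_grid):
        raise ValueError("WTP grid must be non-negative")
    return [
        (float(w), float(np.mean(delta_cost - w * delta_qalys > 0))) for w in wtp_grid
    ]


def run_psa(
    params: ParameterSet,
    n: int = 5000,
    seed: int = 0,
    comparators: tuple[str, ...] = ("NRLF", "RLF"),
    reference: str = "HF10",
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model."""
    if n <= 0:
        raise ValueError("n must be a positive integer")
    arms = (reference, *comparators)
    costs = {arm: np.empty(n) for arm in arms}
    qalys = {arm: np.empty(n) for arm in arms}
    for i in range(n):
        sampled = sample_parameter_set(params, seed, i)
        for arm in arms:
            res = evaluate_arm(sampled, arm)
            costs[arm][i] = res.total_cost
            qalys[arm][i] = res.total_qalys

    summaries: dict[str, ComparisonSummary] = {}
    for comp in comparators:
        d_cost = costs[comp] - costs[reference]
        d_qalys = qalys[comp] - qalys[reference]
        mean = float(d_cost.mean())
        half = 0.0 if n < 2 else 1.96 * float(d_cost.std(ddof=1)) / np.sqrt(n)
        summaries[comp] = ComparisonSummary(
            comparator=comp,
            prob_cost_saving=float(np.mean(d_cost > 0)),
            mean_delta_cost=mean,
            mean_delta_cost_ci=(mean - half, mean + half),
            mean_delta_cost_percentile_ci=(
                float(np.percentile(d_cost, 2.5)),
                float(np.percentile(d_cost, 97.5)),
            ),
            mean_delta_qalys=float(d_qalys.mean()),
            ceac=ceac(d_cost, d_qalys, wtp_grid),
        )
    return PSAResult(n_draws=n, seed=seed, comparisons=summaries, costs=costs, qalys=qalys)
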