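"""Synthetic patient-level trial records and re-estimation of model inputs.

The clinical inputs of the model come from a patient-level analysis of a
two-arm randomised trial (10 kHz high-frequency vs low-frequency SCS, ~100
patients per arm, 24-month follow-up).  That dataset is proprietary; this
module simulates records with the same probabilistic structure — per-patient
screening-trial success, 6-month responder status (>=50% leg-pain
reduction), early and late non-serious complications, and device explant
times over 24 months from a two-piece constant-hazard model matching the
Year-1 and Year-2 annual explant probabilities — and re-estimates the
model's input probabilities with Wald 95% confidence intervals, providing a
parameter-recovery surface for the whole pipeline.

Conventions (documented because the source's denominators are not printed):
responder/complication outcomes exist only for permanently implanted
patients (screening successes) and use all implanted patients as the
denominator; Year-1 explant probability is estimated among all implanted
patients, Year-2 among those still implanted at month 12.  Explant reasons
are paresthesia-weighted in Year 1 and weighted towards ineffective pain
control in Year 2, mirroring the reported pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ArmParameters

__all__ = [
    "PatientRecord",
    "EstimatedInputs",
    "Estimate",
    "simulate_trial",
    "records_to_frame",
    "estimate_inputs",
]

#: explant-reason sampling weights (ineffective_pain, paresthesia, other)
REASON_WEIGHTS_YR1 = (0.25, 0.55, 0.20)
REASON_WEIGHTS_YR2 = (0.60, 0.20, 0.20)
_REASONS = ("ineffective_pain", "paresthesia", "other")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    arm: str  # "HF10" | "LF"
    trial_success: bool
    responder_6mo: bool | None
    complication_6mo: bool | None
    complication_late: bool | None
    explant_month: int | None  # month of explant in [0, 24), None if none
    explant_reason: str | None

    def __post_init__(self) -> None:
        if (self.explant_month is None) != (self.explant_reason is None):
            raise ValueError("explant fields must be jointly present or absent")
        if not self.trial_success and self.responder_6mo is not None:
            raise ValueError("responder status exists only for implanted patients")


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a Wald 95% CI (clipped to [0, 1])."""

    value: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int

    @classmethod
    def from_counts(cls, k: int, n: int) -> "Estimate":
        if n == 0:
            # undefined, not zero
            return cls(None, None, None, k, 0)
        p = k / n
        half = 1.96 * math.sqrt(p * (1 - p) / n)
        return cls(p, max(0.0, p - half), min(1.0, p + half), k, n)

    def covers(self, truth: float) -> bool:
        return self.value is not None and self.ci_low <= truth <= self.ci_high


@dataclass
class EstimatedInputs:
    """Re-estimated model inputs per arm, Table-style (value + 95% CI)."""

    per_arm: dict[str, dict[str, Estimate]]

    FIELDS = (
        "trial_success",
        "p_optimal_6mo",
        "p_complication_6mo",
        "explant_yr1",
        "explant_yr2",
        "p_complication_late",
    )

    def point_estimates(self, arm: str) -> dict[str, float | None]:
        return {f: e.value for f, e in self.per_arm[arm].items()}


def _draw_explant_month(
    rng: np.random.Generator, explant_yr1: float, explant_yr2: float
) -> int | None:
    """Explant month under a two-piece constant-hazard model over 24 months."""
    # monthly hazards matching the annual probabilities
    lam1 = -math.log(1.0 - explant_yr1) / 12.0 if explant_yr1 < 1 else math.inf
    lam2 = -math.log(1.0 - explant_yr2) / 12.0 if explant_yr2 < 1 else math.inf
    t = rng.exponential(1.0 / lam1) if lam1 > 0 else math.inf
    if t >= 12.0:
        if lam2 <= 0:
            return None
        t = 12.0 + rng.exponential(1.0 / lam2)
    if t >= 24.0:
        return None
    return int(t)


def simulate_trial(
    true_params: dict[str, ArmParameters], n_per_arm: int, seed: int
) -> list[PatientRecord]:
    """Simulate ``n_per_arm`` patients per arm; deterministic given ``seed``."""
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    records: list[PatientRecord] = []
    for arm_idx, (arm, ap) in enumerate(sorted(true_params.items())):
        rng = np.random.default_rng([int(seed), arm_idx])
        for i in range(n_per_arm):
            pid = f"{arm}-{i:06d}"
            success = bool(rng.random() < ap.trial_success)
            if not success:
                records.append(
                    PatientRecord(pid, arm, False, None, None, None, None, None)
                )
                continue
            responder = bool(rng.random() < ap.p_optimal_6mo)
            comp6 = bool(rng.random() < ap.p_complication_6mo)
            comp_late = bool(rng.random() < ap.p_complication_late)
            month = _draw_explant_month(rng, ap.explant_yr1, ap.explant_yr2)
            reason = None
            if month is not None:
                weights = REASON_WEIGHTS_YR1 if month < 12 else REASON_WEIGHTS_YR2
                reason = _REASONS[rng.choice(3, p=weights)]
            records.append(
                PatientRecord(pid, arm, True, responder, comp6, comp_late, month, reason)
            )
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Record list as a DataFrame (CSV-ready, documented column order)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "arm": r.arm,
                "trial_success": r.trial_success,
                "responder_6mo": r.responder_6mo,
                "complication_6mo": r.complication_6mo,
                "complication_late": r.complication_late,
                "explant_month": r.explant_month,
                "explant_reason": r.explant_reason,
            }
            for r in records
        ]
    )


def estimate_inputs(records: list[PatientRecord]) -> EstimatedInputs:
    """Proportions with Wald 95% CIs, per arm, from simulated records."""
    if not records:
        raise ValueError("no records supplied")
    per_arm: dict[str, dict[str, Estimate]] = {}
    for arm in sorted({r.arm for r in records}):
        recs = [r for r in records if r.arm == arm]
        implanted = [r for r in recs if r.trial_success]
        n, n_impl = len(recs), len(implanted)
        explants_yr1 = sum(
            1 for r in implanted if r.explant_month is not None and r.explant_month < 12
        )
        at_risk_yr2 = n_impl - explants_yr1
        explants_yr2 = sum(
            1 for r in implanted
            if r.explant_month is not None and 12 <= r.explant_month < 24
        )
        per_arm[arm] = {
            "trial_success": Estimate.from_counts(n_impl, n),
            "p_optimal_6mo": Estimate.from_counts(
                sum(bool(r.responder_6mo) for r in implanted), n_impl
            ),
            "p_complication_6mo": Estimate.from_counts(
                sum(bool(r.complication_6mo) for r in implanted), n_impl
            ),
            "explant_yr1": Estimate.from_counts(explants_yr1, n_impl),
            "explant_yr2": Estimate.from_counts(explants_yr2, at_risk_yr2),
            "p_complication_late": Estimate.from_counts(
                sum(bool(r.complication_late) for r in implanted), n_impl
            ),
        }
    return EstimatedInputs(per_arm=per_arm)
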