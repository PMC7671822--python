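"""Model parameters, configuration loading, and numeric primitives.

The model compares three spinal-cord-stimulation (SCS) strategies for chronic
back and leg pain — 10 kHz high-frequency SCS (``HF10``), non-rechargeable
low-frequency SCS (``NRLF``) and rechargeable low-frequency SCS (``RLF``) —
from a UK NHS perspective in 2016 GBP.  All inputs are point estimates with
95% confidence intervals (or plausible ranges); probabilistic analyses sample
probabilities and utilities from beta distributions and costs / device
longevity from gamma distributions, each moment-matched to the printed CI.

This module owns:

* the validated parameter containers (:class:`ArmParameters`,
  :class:`SharedParameters`, :class:`UtilitySet`, :class:`ParameterSet`);
* loading/overriding the JSON configuration (a packaged default encodes the
  base case);
* rate/probability conversion and discounting primitives;
* method-of-moments beta/gamma fits from a mean and a 95% CI.
"""

from __future__ import annotations

import copy
import json
from importlib import resources
from typing import Any, Iterator, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "ARM_NAMES",
    "ConfigError",
    "FitError",
    "DistributionSpec",
    "ArmParameters",
    "SharedParameters",
    "UtilitySet",
    "ParameterSet",
    "load_parameters",
    "load_default_parameters",
    "annual_to_cycle_probability",
    "discount_factor",
    "fit_beta_from_ci",
    "fit_gamma_from_ci",
]

ARM_NAMES = ("HF10", "NRLF", "RLF")

#: divisor converting a symmetric 95% CI width to a standard error (2 * 1.96)
CI_WIDTH_TO_SE = 3.92


class ConfigError(ValueError):
    """Configuration file is missing fields or violates an invariant."""


class FitError(ValueError):
    """A distribution cannot be moment-matched to the requested mean/CI.

    Callers sampling from the distribution should fall back to a uniform
    draw on ``[ci_low, ci_high]``.
    """


# ---------------------------------------------------------------------------
# numeric primitives
# ---------------------------------------------------------------------------


def annual_to_cycle_probability(p_annual: float, cycle_length_years: float) -> float:
    """Convert an annual event probability to a per-cycle probability.

    Assumes a constant hazard within the year, so the per-cycle probability
    is ``1 - (1 - p_annual) ** cycle_length_years``.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must lie in [0, 1], got {p_annual}")
    if cycle_length_years <= 0:
        raise ValueError("cycle_length_years must be positive")
    return 1.0 - (1.0 - p_annual) ** cycle_length_years


def discount_factor(t_years: float, rate: float) -> float:
    """Discrete-time discount factor ``(1 + rate) ** -t`` at time ``t`` years."""
    if t_years < 0:
        raise ValueError("t_years must be non-negative")
    return (1.0 + rate) ** (-t_years)


def fit_beta_from_ci(mean: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Method-of-moments beta fit from a mean and a 95% CI.

    The CI width is converted to a standard error with the normal
    approximation ``SE = (ci_high - ci_low) / 3.92``; then
    ``nu = mean (1 - mean) / SE^2 - 1`` and ``alpha = mean * nu``,
    ``beta = (1 - mean) * nu``.  The fitted mean reproduces the input mean
    exactly.

    Raises
    ------
    FitError
        If the CI is too wide for the mean (``nu <= 0``); sample from a
        uniform on ``[ci_low, ci_high]`` instead.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie strictly in (0, 1), got {mean}")
    if not ci_low < ci_high:
        raise ValueError("ci_low must be < ci_high")
    se = (ci_high - ci_low) / CI_WIDTH_TO_SE
    nu = mean * (1.0 - mean) / se**2 - 1.0
    if nu <= 0:
        raise FitError(
            f"CI ({ci_low}, {ci_high}) too wide for beta mean {mean}; "
            "fall back to uniform sampling on [ci_low, ci_high]"
        )
    return mean * nu, (1.0 - mean) * nu


def fit_gamma_from_ci(mean: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Method-of-moments gamma fit (shape, scale) from a mean and a 95% CI.

    ``SE = (ci_high - ci_low) / 3.92``; ``shape = mean^2 / SE^2``,
    ``scale = SE^2 / mean``.  ``shape * scale`` reproduces the mean exactly.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if not ci_low < ci_high:
        raise ValueError("ci_low must be < ci_high")
    se = (ci_high - ci_low) / CI_WIDTH_TO_SE
    return mean**2 / se**2, se**2 / mean


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class DistributionSpec(BaseModel):
    """A sampled parameter: base-case value, 95% CI, and sampling family."""

    model_config = ConfigDict(frozen=True)

    name: str
    base_value: float
    ci_low: float
    ci_high: float
    family: Literal["beta", "gamma", "fixed"]

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        if not self.ci_low <= self.base_value <= self.ci_high:
            raise ValueError(
                f"{self.name}: base value {self.base_value} outside "
                f"CI [{self.ci_low}, {self.ci_high}]"
            )
        if self.family == "beta" and not (0.0 <= self.ci_low and self.ci_high <= 1.0):
            raise ValueError(f"{self.name}: beta CI must lie within [0, 1]")
        if self.family == "gamma" and self.ci_low < 0:
            raise ValueError(f"{self.name}: gamma CI lower bound must be >= 0")
        return self

    @property
    def is_sampled(self) -> bool:
        return self.family != "fixed" and self.ci_low < self.ci_high


def _prob(default: Any = ...) -> Any:
    return Field(default, ge=0.0, le=1.0)


class ArmParameters(BaseModel):
    """Clinical and device parameters specific to one treatment arm.

    The two low-frequency arms share all clinical probabilities (trial
    success, response, complications, explants); they differ only in implant
    cost and device longevity.
    """

    model_config = ConfigDict(frozen=True)

    arm: Literal["HF10", "NRLF", "RLF"]
    trial_success: float = _prob()
    p_optimal_6mo: float = _prob()
    p_complication_6mo: float = _prob()
    explant_yr1: float = _prob()
    explant_yr2: float = _prob()
    explant_yr3plus: float = _prob()
    p_complication_late: float = _prob()
    device_longevity_years: float = Field(gt=0.0)
    cost_implant: float = Field(ge=0.0)
    cost_reimplant: Optional[float] = Field(None, ge=0.0)

    @property
    def reimplant_cost(self) -> float:
        """Replacement-system cost; defaults to the permanent implant cost."""
        return self.cost_implant if self.cost_reimplant is None else self.cost_reimplant


class SharedParameters(BaseModel):
    """Parameters common to every arm: CMM pathway, mortality, costs, run settings."""

    model_config = ConfigDict(frozen=True)

    p_optimal_cmm_6mo: float = _prob()
    annual_mortality: float = _prob()
    p_reoperation: float = _prob()
    p_optimal_post_reop: float = _prob()
    cost_trial: float = Field(ge=0.0)
    cost_failed_trial_removal: float = Field(ge=0.0)
    cost_explant: float = Field(ge=0.0)
    cost_complication: float = Field(ge=0.0)
    cost_drug_cmm_6mo: float = Field(ge=0.0)
    cost_nondrug_cmm_6mo: float = Field(ge=0.0)
    cost_drug_scs_6mo: float = Field(ge=0.0)
    cost_nondrug_scs_6mo: float = Field(ge=0.0)
    cost_reoperation: float = Field(0.0, ge=0.0)
    discount_rate: float = Field(ge=0.0)
    horizon_years: float = Field(gt=0.0)
    cycle_length_years: float = Field(gt=0.0, le=1.0)
    wtp_per_qaly: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "SharedParameters":
        n = self.horizon_years / self.cycle_length_years
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "horizon_years must be an integer multiple of cycle_length_years"
            )
        return self


class UtilitySet(BaseModel):
    """Health-state utilities (EQ-5D style, on [0, 1])."""

    model_config = ConfigDict(frozen=True)

    u_opt_nc: float = _prob()
    u_opt_c: float = _prob()
    u_subopt_nc: float = _prob()
    u_subopt_c: float = _prob()
    u_no_relief: float = _prob()

    def check_ordering(self) -> None:
        """Complication states must not be valued above complication-free ones.

        Enforced for explicitly configured utilities; independently sampled
        draws may cross (the marginals overlap) and are accepted.
        """
        if self.u_opt_c > self.u_opt_nc:
            raise ValueError("u_opt_c must not exceed u_opt_nc")
        if self.u_subopt_c > self.u_subopt_nc:
            raise ValueError("u_subopt_c must not exceed u_subopt_nc")


class ParameterSet(BaseModel):
    """Complete, validated model configuration.

    ``specs`` maps each parameter's dotted configuration path (e.g.
    ``clinical.hf.trial_success`` or ``shared.cost_trial``) to its
    :class:`DistributionSpec`; parameters under ``clinical.lf`` are shared
    between the NRLF and RLF arms, so one draw feeds both.
    """

    model_config = ConfigDict(frozen=True)

    arms: dict[str, ArmParameters]
    shared: SharedParameters
    utilities: UtilitySet
    specs: dict[str, DistributionSpec]
    raw: dict[str, Any] = Field(repr=False)

    @model_validator(mode="after")
    def _check(self) -> "ParameterSet":
        if set(self.arms) != set(ARM_NAMES):
            raise ValueError(f"arms must be exactly {set(ARM_NAMES)}, got {set(self.arms)}")
        for name, arm in self.arms.items():
            if arm.arm != name:
                raise ValueError(f"arm key {name!r} does not match identifier {arm.arm!r}")
        return self

    def with_overrides(self, overrides: dict[str, float]) -> "ParameterSet":
        """Return a new ParameterSet with named parameters replaced.

        Keys are dotted configuration paths as listed in :attr:`specs`
        (plus fixed settings such as ``shared.horizon_years``).  Overriding
        ``arms.<ARM>.cost_reimplant`` on a config where it is null (meaning
        "same as implant") installs an explicit fixed value.
        """
        raw = copy.deepcopy(self.raw)
        for path, value in overrides.items():
            node = raw
            parts = path.split(".")
            for part in parts[:-1]:
                if part not in node:
                    raise ConfigError(f"unknown parameter path {path!r}")
                node = node[part]
            leaf = parts[-1]
            if leaf not in node:
                raise ConfigError(f"unknown parameter path {path!r}")
            if node[leaf] is None:
                node[leaf] = {"value": float(value), "family": "fixed"}
            else:
                node[leaf]["value"] = float(value)
                ci = node[leaf].get("ci")
                if ci is not None:
                    # keep the invariant ci_low <= value <= ci_high for
                    # overrides (e.g. sampled draws) outside the printed CI
                    ci[0] = min(ci[0], float(value))
                    ci[1] = max(ci[1], float(value))
        return parameter_set_from_dict(raw, validate_utility_ordering=False)

    def base_value(self, path: str) -> float:
        """Base-case value of a parameter identified by its dotted path."""
        node: Any = self.raw
        for part in path.split("."):
            if not isinstance(node, dict) or part not in node:
                raise ConfigError(f"unknown parameter path {path!r}")
            node = node[part]
        if node is None:
            raise ConfigError(f"parameter {path!r} has no explicit value")
        return float(node["value"])


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

_CLINICAL_FIELDS = (
    "trial_success",
    "p_optimal_6mo",
    "p_complication_6mo",
    "explant_yr1",
    "explant_yr2",
    "explant_yr3plus",
    "p_complication_late",
)


def _entry_value(section: str, name: str, entry: Any) -> float:
    if not isinstance(entry, dict) or "value" not in entry:
        raise ConfigError(f"{section}.{name}: expected an object with a 'value' field")
    return float(entry["value"])


def _iter_spec_entries(raw: dict[str, Any]) -> Iterator[tuple[str, dict[str, Any]]]:
    for group, block in raw.get("clinical", {}).items():
        for name, entry in block.items():
            yield f"clinical.{group}.{name}", entry
    for arm, block in raw.get("arms", {}).items():
        for name in ("cost_implant", "cost_reimplant", "device_longevity_years"):
            entry = block.get(name)
            if isinstance(entry, dict):
                yield f"arms.{arm}.{name}", entry
    for section in ("shared", "utilities"):
        for name, entry in raw.get(section, {}).items():
            yield f"{section}.{name}", entry


def parameter_set_from_dict(
    raw: dict[str, Any], validate_utility_ordering: bool = True
) -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from a parsed configuration."""
    if raw.get("schema_version") != 1:
        raise ConfigError("configuration must declare schema_version = 1")
    for section in ("clinical", "arms", "shared", "utilities"):
        if section not in raw:
            raise ConfigError(f"configuration missing section {section!r}")

    specs: dict[str, DistributionSpec] = {}
    for path, entry in _iter_spec_entries(raw):
        value = _entry_value(*path.rsplit(".", 1), entry)
        family = entry.get("family", "fixed")
        ci = entry.get("ci", [value, value])
        try:
            specs[path] = DistributionSpec(
                name=path, base_value=value, ci_low=ci[0], ci_high=ci[1], family=family
            )
        except ValidationError as exc:
            raise ConfigError(f"invalid parameter {path}: {exc}") from exc

    def values(section: str, block: dict[str, Any]) -> dict[str, float]:
        return {name: _entry_value(section, name, entry) for name, entry in block.items()}

    try:
        arms: dict[str, ArmParameters] = {}
        for arm_name, block in raw["arms"].items():
            clin_key = block.get("clinical")
            if clin_key not in raw["clinical"]:
                raise ConfigError(
                    f"arms.{arm_name}.clinical refers to unknown block {clin_key!r}"
                )
            clinical = values(f"clinical.{clin_key}", raw["clinical"][clin_key])
            missing = [f for f in _CLINICAL_FIELDS if f not in clinical]
            if missing:
                raise ConfigError(f"clinical.{clin_key} missing fields: {missing}")
            reimplant = block.get("cost_reimplant")
            arms[arm_name] = ArmParameters(
                arm=arm_name,
                **clinical,
                cost_implant=_entry_value(arm_name, "cost_implant", block["cost_implant"]),
                cost_reimplant=(
                    None if reimplant is None
                    else _entry_value(arm_name, "cost_reimplant", reimplant)
                ),
                device_longevity_years=_entry_value(
                    arm_name, "device_longevity_years", block["device_longevity_years"]
                ),
            )
        shared = SharedParameters(**values("shared", raw["shared"]))
        utilities = UtilitySet(**values("utilities", raw["utilities"]))
        if validate_utility_ordering:
            try:
                utilities.check_ordering()
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
        return ParameterSet(
            arms=arms, shared=shared, utilities=utilities, specs=specs, raw=raw
        )
    except ValidationError as exc:
        # surface the offending field names in a single message
        fields = ", ".join(
            ".".join(str(loc) for loc in err["loc"]) or "<model>" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration (fields: {fields}): {exc}") from exc
    except KeyError as exc:
        raise ConfigError(f"configuration missing field {exc.args[0]!r}") from exc


def load_parameters(config_path: str) -> ParameterSet:
    """Load and validate a model configuration from a JSON file."""
    with open(config_path, "r", encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{config_path} is not valid JSON: {exc}") from exc
    return parameter_set_from_dict(raw)


def load_default_parameters() -> ParameterSet:
    """Load the packaged base-case configuration."""
    text = resources.files("scs_cea").joinpath("config/default_config.json").read_text()
    return parameter_set_from_dict(json.loads(text))
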