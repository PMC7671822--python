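"""Configuration loading, validation, and numeric primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scs_cea.params import (
    ConfigError,
    FitError,
    annual_to_cycle_probability,
    discount_factor,
    fit_beta_from_ci,
    fit_gamma_from_ci,
    parameter_set_from_dict,
)


class TestLoading:
    @pytest.mark.parametrize(
        "path, expected",
        [
            ("clinical.hf.trial_success", 0.928),
            ("clinical.lf.trial_success", 0.880),
            ("clinical.hf.p_optimal_6mo", 0.809),
            ("clinical.lf.explant_yr1", 0.111),
            ("arms.NRLF.cost_implant", 11281),
            ("arms.RLF.device_longevity_years", 10),
            ("shared.cost_trial", 5281),
            ("utilities.u_no_relief", 0.168),
        ],
    )
    def test_default_config_values(self, base_params, path, expected):
        assert base_params.base_value(path) == pytest.approx(expected)

    def test_lf_arms_share_clinical_parameters(self, base_params):
        nrlf, rlf = base_params.arms["NRLF"], base_params.arms["RLF"]
        for f in ("trial_success", "p_optimal_6mo", "explant_yr1", "explant_yr2"):
            assert getattr(nrlf, f) == getattr(rlf, f)
        assert nrlf.device_longevity_years != rlf.device_longevity_years

    def test_probability_out_of_range_is_rejected(self, raw_config):
        raw_config["clinical"]["hf"]["trial_success"]["value"] = 1.2
        raw_config["clinical"]["hf"]["trial_success"]["ci"] = [0.8, 1.3]
        with pytest.raises(ConfigError, match="trial_success"):
            parameter_set_from_dict(raw_config)

    def test_missing_field_is_named(self, raw_config):
        del raw_config["shared"]["cost_trial"]
        with pytest.raises(ConfigError, match="cost_trial"):
            parameter_set_from_dict(raw_config)

    def test_reimplant_defaults_to_implant_cost(self, base_params):
        for arm in base_params.arms.values():
            assert arm.cost_reimplant is None
            assert arm.reimplant_cost == arm.cost_implant

    def test_utility_ordering_enforced_on_explicit_config(self, raw_config):
        raw_config["utilities"]["u_opt_c"]["value"] = 0.62
        raw_config["utilities"]["u_opt_c"]["ci"] = [0.5, 0.7]
        with pytest.raises(ConfigError, match="u_opt_c"):
            parameter_set_from_dict(raw_config)

    def test_override_returns_new_set(self, base_params):
        p2 = base_params.with_overrides({"shared.cost_trial": 6000})
        assert p2.shared.cost_trial == 6000
        assert base_params.shared.cost_trial == 5281
        with pytest.raises(ConfigError, match="no.such"):
            base_params.with_overrides({"no.such.path": 1.0})


class TestConversions:
    @pytest.mark.parametrize(
        "p, cycle, expected",
        [(0.0, 0.25, 0.0), (1.0, 0.25, 1.0), (0.0081, 0.25, 0.0020312)],
    )
    def test_annual_to_cycle(self, p, cycle, expected):
        assert annual_to_cycle_probability(p, cycle) == pytest.approx(
            expected, abs=5e-7
        )

    def test_annual_to_cycle_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            annual_to_cycle_probability(1.5, 0.25)

    @given(p=st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=60)
    def test_quarterly_survival_composition_recovers_annual(self, p):
        q = annual_to_cycle_probability(p, 0.25)
        assert 1.0 - (1.0 - q) ** 4 == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize(
        "t, rate, expected",
        [(0.0, 0.035, 1.0), (1.0, 0.035, 1 / 1.035), (15.0, 0.035, 0.596891)],
    )
    def test_discount_factor(self, t, rate, expected):
        assert discount_factor(t, rate) == pytest.approx(expected, abs=5e-7)

    def test_discount_factor_monotone_and_rate_zero(self):
        ts = np.linspace(0, 20, 40)
        dfs = [discount_factor(t, 0.035) for t in ts]
        assert all(a > b for a, b in zip(dfs, dfs[1:]))
        assert all(discount_factor(t, 0.0) == 1.0 for t in ts)
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035)


class TestDistributionFits:
    def test_beta_symmetric_example(self):
        # mean 0.5 with SE 0.05 (CI width 0.196)
        a, b = fit_beta_from_ci(0.5, 0.402, 0.598)
        assert a == pytest.approx(49.5, rel=1e-9)
        assert b == pytest.approx(49.5, rel=1e-9)

    def test_beta_trial_success_example(self):
        a, b = fit_beta_from_ci(0.928, 0.876, 0.979)
        assert a == pytest.approx(88.88, rel=1e-3)
        assert b == pytest.approx(6.896, rel=1e-3)
        # fitted moments reproduce the inputs
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(0.928, abs=1e-12)
        assert math.sqrt(var) == pytest.approx((0.979 - 0.876) / 3.92, abs=1e-9)

    def test_beta_monte_carlo_mean(self):
        a, b = fit_beta_from_ci(0.928, 0.876, 0.979)
        draws = np.random.default_rng(0).beta(a, b, 100_000)
        assert draws.mean() == pytest.approx(0.928, abs=0.002)

    def test_beta_too_wide_raises_fit_error(self):
        # SE 0.255 exceeds the maximum SD of a beta with mean 0.98
        with pytest.raises(FitError, match="uniform"):
            fit_beta_from_ci(0.98, 0.0, 1.0)

    def test_gamma_unit_example(self):
        # mean 100, SE 10 (CI width 39.2)
        shape, scale = fit_gamma_from_ci(100, 80.4, 119.6)
        assert shape == pytest.approx(100, rel=1e-9)
        assert scale == pytest.approx(1.0, rel=1e-9)

    def test_gamma_trial_cost_example(self):
        shape, scale = fit_gamma_from_ci(5281, 3441, 7931)
        se = (7931 - 3441) / 3.92
        assert shape == pytest.approx((5281 / se) ** 2, rel=1e-12)
        assert shape * scale == pytest.approx(5281, abs=1e-9)

    def test_gamma_reproduces_mean_for_every_cost_row(self, base_params):
        for name, spec in base_params.specs.items():
            if spec.family != "gamma" or not spec.is_sampled:
                continue
            shape, scale = fit_gamma_from_ci(
                spec.base_value, spec.ci_low, spec.ci_high
            )
            assert shape * scale == pytest.approx(spec.base_value, rel=1e-12), name

    @given(
        mean=st.floats(0.05, 0.95),
        width=st.floats(0.01, 0.5),
    )
    @settings(derandomize=True, max_examples=60)
    def test_beta_moment_round_trip(self, mean, width):
        se = width / 3.92
        lo, hi = mean - width / 2, mean + width / 2
        if lo < 0 or hi > 1 or mean * (1 - mean) / se**2 - 1 <= 0:
            return
        a, b = fit_beta_from_ci(mean, lo, hi)
        fitted_mean = a / (a + b)
        fitted_sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        assert fitted_mean == pytest.approx(mean, abs=1e-9)
        assert fitted_sd == pytest.approx(se, abs=1e-9)

    @given(mean=st.floats(1.0, 1e5), rel_width=st.floats(0.05, 3.0))
    @settings(derandomize=True, max_examples=60)
    def test_gamma_moment_round_trip(self, mean, rel_width):
        lo, hi = mean, mean * (1 + rel_width)
        shape, scale = fit_gamma_from_ci(mean, lo, hi)
        se = (hi - lo) / 3.92
        assert shape * scale == pytest.approx(mean, rel=1e-9)
        assert math.sqrt(shape) * scale == pytest.approx(se, rel=1e-9)
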