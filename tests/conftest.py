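import copy

import pytest

from scs_cea.params import load_default_parameters, parameter_set_from_dict


@pytest.fixture(scope="session")
def base_params():
    return load_default_parameters()


@pytest.fixture()
def raw_config(base_params):
    """A mutable copy of the default configuration dictionary."""
    return copy.deepcopy(base_params.raw)


@pytest.fixture(scope="session")
def hazard_free_params(base_params):
    """All transition hazards switched off (mortality, explants, complications)."""
    return base_params.with_overrides(
        {
            "shared.annual_mortality": 0.0,
            "clinical.hf.explant_yr1": 0.0,
            "clinical.hf.explant_yr2": 0.0,
            "clinical.hf.explant_yr3plus": 0.0,
            "clinical.hf.p_complication_late": 0.0,
            "clinical.lf.explant_yr1": 0.0,
            "clinical.lf.explant_yr2": 0.0,
            "clinical.lf.explant_yr3plus": 0.0,
            "clinical.lf.p_complication_late": 0.0,
        }
    )


def make_params(raw):
    return parameter_set_from_dict(raw)
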