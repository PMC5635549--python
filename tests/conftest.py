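import logging

import pytest

from prekcea.engine import make_gompertz_lifetable
from prekcea.parameters import ParamRegistry, ScenarioConfig, load_registry

logging.getLogger("prekcea.parameters").setLevel(logging.ERROR)

# The four intervention-effect odds ratios; forcing them to 1 makes the two
# arms statistically (and, under common random numbers, bit-) identical.
PC_EFFECT_ORS = (
    "or_pc_behavior",
    "or_pc_academic",
    "or_pc_obese_low_self_reg",
    "or_pc_obese_no_low_self_reg",
)


@pytest.fixture(scope="session")
def registry() -> ParamRegistry:
    return load_registry()


@pytest.fixture(scope="session")
def lifetable():
    return make_gompertz_lifetable()


@pytest.fixture()
def base_config() -> ScenarioConfig:
    return ScenarioConfig(n_individuals=1000, seed=7)


def null_intervention(registry: ParamRegistry) -> ParamRegistry:
    """Registry with every intervention-effect OR forced to 1."""
    for name in PC_EFFECT_ORS:
        registry = registry.override(name, 1.0)
    return registry


def zero_disease_registry(registry: ParamRegistry) -> ParamRegistry:
    """Registry in which no childhood or adult event can ever occur."""
    zeroed = (
        "odds_child_academic", "odds_child_obese", "odds_child_behavior",
        "odds_graduate_hs", "odds_child_drug", "odds_child_diabetes",
        "odds_child_judiciary",
        "odds_adult_obesity_incidence", "odds_adult_drug_incidence",
        "odds_adult_diabetes_incidence", "odds_adult_judiciary_incidence",
        "odds_adult_psych_incidence", "odds_adult_cvd_incidence",
    )
    for name in zeroed:
        registry = registry.override(name, 0.0)
    return registry
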