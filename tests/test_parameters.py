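"""Registry contents, validation, overrides, serialization, config parsing."""

import textwrap

import pytest
from pydantic import ValidationError

from prekcea.parameters import (
    ParamRegistry,
    ParamSpec,
    ScenarioConfig,
    load_config,
    load_registry,
    override,
    validate_registry,
)

# Every printed model-input literal, band values listed separately.
# name -> point value, or name -> {(age_lo, age_hi): value} for banded inputs.
PRINTED_INPUTS = {
    "odds_child_academic": 1.35,
    "odds_child_obese": 0.146,
    "odds_child_low_self_reg": 0.33,
    "odds_child_behavior": 0.275,
    "odds_graduate_hs": 2.125,
    "odds_child_drug": 0.13,
    "odds_child_diabetes": 0.001,
    "odds_child_judiciary": 0.099,
    "or_pc_academic": 1.52,
    "or_academic_given_behavior": 0.229,
    "or_obese_given_low_self_reg": 3.846,
    "or_pc_obese_low_self_reg": 0.26,
    "or_pc_obese_no_low_self_reg": 1.0,
    "or_pc_behavior": 0.59,
    "or_behavior_given_low_self_reg": 3.8,
    "or_graduate_given_academic": 1.335,
    "or_graduate_given_drug": 0.699,
    "or_graduate_given_behavior": 0.18,
    "or_child_drug_given_behavior": 3.8,
    "or_child_diabetes_given_obese": 5.1,
    "or_child_judiciary_given_drug": 5.7,
    "or_child_judiciary_given_behavior": 2.925,
    "odds_adult_obesity_incidence": {(18, 39): 0.003, (40, 59): 0.005,
                                     (60, 105): -0.002},
    "odds_adult_drug_incidence": 0.007,
    "odds_adult_diabetes_incidence": 0.0069,
    "odds_employment": 12.7,
    "or_adult_diabetes_given_obese": 7.37,
    "odds_adult_judiciary_incidence": 0.002,
    "odds_adult_psych_incidence": 0.007,
    "odds_adult_cvd_incidence": {(18, 44): 0.004, (45, 54): 0.007,
                                 (55, 64): 0.015, (65, 74): 0.028,
                                 (75, 84): 0.052, (85, 105): 0.075},
    "or_cvd_given_diabetes": 2.3,
    "or_cvd_given_obese": 2.3,
    "or_psych_given_drug": 4.5,
    "or_adult_judiciary_given_drug": 4.14,
    "or_judiciary_persistence": 227.0,
    "or_employment_given_graduated": 1.88,
    "or_employment_given_judiciary_last_year": 0.029,
    "or_drug_persistence": 47.6,
    "or_obesity_persistence": 331.0,
    "cost_drug_treatment": 1000.0,
    "cost_drug_complication": 21483.0,
    "cost_diabetes_treatment": 9975.0,
    "cost_diabetes_complication": 1575.0,
    "cost_obesity_treatment": 0.0,
    "cost_obesity_complication": 732.0,
    "cost_incarceration": 28893.0,
    "cost_unemployment": 33160.0,
    "pc_annual_cost_per_child": 500.0,
    "pc_capacity_cost_per_school": 100000.0,
    "utility_diabetes": 0.690,
    "utility_diabetes_complications": 0.350,
    "utility_drug": 0.670,
    "utility_drug_complications": 0.600,
    "utility_obese": 0.710,
    "utility_obesity_complications": 0.500,
    "utility_prison": 0.725,
}


class TestDefaults:
    def test_worked_values(self, registry):
        assert registry.value("odds_graduate_hs") == 2.125
        assert registry.value("utility_diabetes_complications") == 0.350

    def test_completeness_against_manifest(self, registry):
        """Every printed input appears exactly once with the printed value."""
        n_literals = 0
        for name, expected in PRINTED_INPUTS.items():
            spec = registry[name]
            if isinstance(expected, dict):
                assert spec.age_bands is not None, name
                got = {(b.age_lo, b.age_hi): b.value for b in spec.age_bands}
                assert got == pytest.approx(expected), name
                n_literals += len(expected)
            else:
                assert spec.age_bands is None, name
                assert spec.value == pytest.approx(expected), name
                n_literals += 1
        assert n_literals >= 60

    def test_missing_ranges_defaulted(self, registry):
        spec = registry["or_obesity_persistence"]
        assert spec.low == pytest.approx(331.0 * 0.5)
        assert spec.high == pytest.approx(331.0 * 1.5)
        # utility upper bounds never exceed 1
        assert registry["utility_prison"].high <= 1.0

    def test_validation_flags_only_the_known_exception(self, registry):
        problems = validate_registry(registry)
        assert len(problems) == 1
        assert "odds_adult_obesity_incidence" in problems[0]
        assert "-0.002" in problems[0]

    def test_age_bands_tile_adult_range(self, registry):
        for name in ("odds_adult_obesity_incidence", "odds_adult_cvd_incidence"):
            bands = sorted(registry[name].age_bands, key=lambda b: b.age_lo)
            assert bands[0].age_lo == 18
            assert bands[-1].age_hi == 105
            for a, b in zip(bands, bands[1:]):
                assert b.age_lo == a.age_hi + 1


class TestOverride:
    def test_override_changes_only_target(self, registry):
        reg2 = override(registry, "or_pc_behavior", 1.0)
        assert reg2.value("or_pc_behavior") == 1.0
        assert registry.value("or_pc_behavior") == 0.59  # original untouched
        assert {n: reg2[n] for n in reg2 if n != "or_pc_behavior"} == \
               {n: registry[n] for n in registry if n != "or_pc_behavior"}

    def test_override_round_trip(self, registry):
        reg2 = override(override(registry, "cost_incarceration", 1.0),
                        "cost_incarceration", 28893.0)
        assert reg2 == registry

    def test_unknown_name_lists_valid_names(self, registry):
        with pytest.raises(KeyError, match="valid names"):
            override(registry, "nonexistent", 1.0)

    def test_banded_override_rescales_bands(self, registry):
        reg2 = override(registry, "odds_adult_cvd_incidence", 0.008)
        bands = {b.age_lo: b.value for b in reg2["odds_adult_cvd_incidence"].age_bands}
        assert bands[18] == pytest.approx(0.008)
        assert bands[45] == pytest.approx(0.014)


class TestValidationRules:
    def test_utility_out_of_unit_interval(self, registry):
        bad = registry.replace_spec(
            ParamSpec("utility_prison", "utility", 1.2, 0.5, 1.5))
        assert any("utility_prison" in p for p in validate_registry(bad))

    def test_inverted_range(self, registry):
        bad = registry.replace_spec(
            ParamSpec("cost_drug_treatment", "cost_per_year", 1000.0, 1500.0, 500.0))
        assert any("low" in p and "cost_drug_treatment" in p
                   for p in validate_registry(bad))


class TestSerialization:
    def test_csv_round_trip(self, registry, tmp_path):
        path = tmp_path / "registry.csv"
        registry.to_csv(path)
        assert load_registry(path) == registry


class TestConfigFiles:
    def test_yaml_config(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(textwrap.dedent("""\
            scenario:
              n_individuals: 500
              seed: 42
              discount_rate: 0.03
            parameter_overrides:
              or_pc_behavior: 0.75
        """))
        config, reg = load_config(path)
        assert config.n_individuals == 500
        assert config.discount_rate == 0.03
        assert reg.value("or_pc_behavior") == 0.75

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("scenari:\n  seed: 1\n")
        with pytest.raises(ValueError, match="unknown top-level"):
            load_config(path)

    def test_unknown_scenario_key_rejected(self, tmp_path):
        path = tmp_path / "bad2.yaml"
        path.write_text("scenario:\n  discount_rat: 0.03\n")
        with pytest.raises(ValidationError):
            load_config(path)

    def test_unknown_override_rejected(self, tmp_path):
        path = tmp_path / "bad3.yaml"
        path.write_text("parameter_overrides:\n  not_a_param: 1\n")
        with pytest.raises(ValueError, match="unknown parameters"):
            load_config(path)


class TestScenarioConfig:
    def test_base_case_defaults(self):
        cfg = ScenarioConfig()
        assert cfg.n_individuals == 100_000
        assert cfg.discount_rate == 0.05
        assert cfg.school_size == 72
        assert cfg.pct_low_self_reg == 0.25
        assert cfg.capacity_durability == 5

    @pytest.mark.parametrize("kwargs", [
        {"n_individuals": 0},
        {"discount_rate": 1.0},
        {"discount_rate": -0.01},
        {"school_size": 0},
        {"capacity_durability": 1},
        {"max_age": 17},
    ])
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ScenarioConfig(**kwargs)
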