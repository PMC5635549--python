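"""Model-input registry and scenario configuration.

Every input the model uses — childhood "odds ever" of each event, the
intervention and risk-factor odds ratios, adult annual incidence odds
(some age-banded), annual costs in 2015 $US, and health-state utilities —
lives in a :class:`ParamRegistry` keyed by a stable snake_case name, together
with its plausible range. The registry is immutable-by-convention: overrides
return a modified copy, which is what the sensitivity-analysis engine relies
on.

Scenario-level knobs (cohort size, discount rate, school size, program
costing, life-table source) live in :class:`ScenarioConfig`, a validated
pydantic model that can be read from a YAML/JSON config file with two
sections, ``scenario`` and ``parameter_overrides``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

logger = logging.getLogger(__name__)

Role = Literal[
    "baseline_odds",
    "odds_ratio",
    "annual_odds",
    "cost_per_year",
    "utility",
    "program_cost",
    "mortality_multiplier",
]

__all__ = [
    "AgeBand",
    "ParamSpec",
    "ParamRegistry",
    "ScenarioConfig",
    "load_registry",
    "load_config",
    "override",
    "validate_registry",
    "DEFAULT_MANIFEST",
]


@dataclass(frozen=True)
class AgeBand:
    """One age band of an age-dependent annual-odds input (inclusive ends)."""

    age_lo: int
    age_hi: int
    value: float
    low: float
    high: float


@dataclass(frozen=True)
class ParamSpec:
    """A single named model input with its plausible range.

    ``low <= value <= high`` is expected for every parameter with a printed
    range; the one deliberate exception in the default registry is the
    over-60 obesity incidence, whose point value (-0.002/yr) encodes net
    remission and lies below its printed lower bound of 0. It is stored as
    printed and flagged by :func:`validate_registry`.
    """

    name: str
    role: Role
    value: float
    low: float
    high: float
    age_bands: tuple[AgeBand, ...] | None = None
    note: str = ""

    def band_value(self, age: int) -> float:
        """Value applying at ``age`` (for age-banded inputs)."""
        if self.age_bands is None:
            return self.value
        for band in self.age_bands:
            if band.age_lo <= age <= band.age_hi:
                return band.value
        raise KeyError(f"{self.name}: no age band covers age {age}")


def _bands(*rows: tuple[int, int, float, float, float]) -> tuple[AgeBand, ...]:
    return tuple(AgeBand(*row) for row in rows)


# Default manifest: one entry per printed model input. Ranges printed as
# "N/A" (program costs) are stored fixed (low == high == value); missing
# ranges elsewhere fall back to +/-50% at load time with a logged warning
# (utility highs clipped at 1).
_RAW_DEFAULTS: list[ParamSpec] = [
    # -- childhood baseline odds ("odds ever", one draw for the 13-yr phase)
    ParamSpec("odds_child_academic", "baseline_odds", 1.35, 0.7, 2.0,
              note="good academic achievement; point prevalence 57.5%"),
    ParamSpec("odds_child_obese", "baseline_odds", 0.146, 0.09, 0.3,
              note="childhood obesity (BMI >= 95th pct); stored as printed"),
    ParamSpec("odds_child_low_self_reg", "baseline_odds", 0.33, 0.15, 0.4,
              note="low self-regulation; base-case sampling uses the scenario prevalence instead"),
    ParamSpec("odds_child_behavior", "baseline_odds", 0.275, 0.14, 0.4,
              note="behavior problems; period prevalence 21.6%"),
    ParamSpec("odds_graduate_hs", "baseline_odds", 2.125, 1.59, 2.66,
              note="graduating high school; incidence 68%"),
    ParamSpec("odds_child_drug", "baseline_odds", 0.13, 0.11, 0.15,
              note="any drug abuse disorder in childhood"),
    ParamSpec("odds_child_diabetes", "baseline_odds", 0.001, 0.0, 0.002,
              note="type 2 diabetes as a child"),
    ParamSpec("odds_child_judiciary", "baseline_odds", 0.099, 0.074, 0.124,
              note="judiciary interaction as a child (one violent-crime arrest)"),
    # -- childhood odds ratios
    ParamSpec("or_pc_academic", "odds_ratio", 1.52, 1.0, 2.43,
              note="academic achievement given intervention"),
    ParamSpec("or_academic_given_behavior", "odds_ratio", 0.229, 0.084, 0.621),
    ParamSpec("or_obese_given_low_self_reg", "odds_ratio", 3.846, 1.36, 4.50),
    ParamSpec("or_pc_obese_low_self_reg", "odds_ratio", 0.26, 0.08, 0.865,
              note="obesity given low self-regulation and intervention"),
    ParamSpec("or_pc_obese_no_low_self_reg", "odds_ratio", 1.0, 0.82, 1.0,
              note="obesity given no low self-regulation and intervention"),
    ParamSpec("or_pc_behavior", "odds_ratio", 0.59, 0.41, 0.85,
              note="behavior problems given intervention"),
    ParamSpec("or_behavior_given_low_self_reg", "odds_ratio", 3.8, 2.0, 5.5),
    ParamSpec("or_graduate_given_academic", "odds_ratio", 1.335, 1.0, 4.0),
    ParamSpec("or_graduate_given_drug", "odds_ratio", 0.699, 0.584, 0.826),
    ParamSpec("or_graduate_given_behavior", "odds_ratio", 0.18, 0.1, 1.0),
    ParamSpec("or_child_drug_given_behavior", "odds_ratio", 3.8, 1.0, 5.0),
    ParamSpec("or_child_diabetes_given_obese", "odds_ratio", 5.1, 1.51, 17.0),
    ParamSpec("or_child_judiciary_given_drug", "odds_ratio", 5.7, 2.30, 15.05),
    ParamSpec("or_child_judiciary_given_behavior", "odds_ratio", 2.925, 1.300, 6.375),
    # -- adult annual odds
    ParamSpec("odds_adult_obesity_incidence", "annual_odds", 0.003, 0.0, 0.064,
              age_bands=_bands((18, 39, 0.003, 0.0, 0.064),
                               (40, 59, 0.005, 0.001, 0.01),
                               (60, 105, -0.002, 0.0, 0.005)),
              note="per-yr obesity incidence; over-60 value is net remission"),
    ParamSpec("odds_adult_drug_incidence", "annual_odds", 0.007, 0.002, 0.013,
              note="per-yr adult drug abuse (alcohol use/dependence)"),
    ParamSpec("odds_adult_diabetes_incidence", "annual_odds", 0.0069, 0.006, 0.008),
    ParamSpec("odds_employment", "annual_odds", 12.7, 9.52, 15.87,
              note="employment odds (drawn once at 18; fixed unless judiciary shock)"),
    ParamSpec("or_adult_diabetes_given_obese", "odds_ratio", 7.37, 6.39, 8.50),
    ParamSpec("odds_adult_judiciary_incidence", "annual_odds", 0.002, 0.0, 0.005),
    ParamSpec("odds_adult_psych_incidence", "annual_odds", 0.007, 0.005, 0.009,
              note="per-yr new psychiatric (mood) disorder"),
    ParamSpec("odds_adult_cvd_incidence", "annual_odds", 0.004, 0.002, 0.006,
              age_bands=_bands((18, 44, 0.004, 0.002, 0.006),
                               (45, 54, 0.007, 0.006, 0.008),
                               (55, 64, 0.015, 0.010, 0.022),
                               (65, 74, 0.028, 0.020, 0.035),
                               (75, 84, 0.052, 0.045, 0.060),
                               (85, 105, 0.075, 0.07, 0.08)),
              note="per-yr CVD incidence; final printed band extended to max age"),
    # -- adult odds ratios
    ParamSpec("or_cvd_given_diabetes", "odds_ratio", 2.3, 1.5, 3.5),
    ParamSpec("or_cvd_given_obese", "odds_ratio", 2.3, 1.5, 3.5,
              note="assumed equal to the diabetes CVD risk"),
    ParamSpec("or_psych_given_drug", "odds_ratio", 4.5, 3.36, 7.38),
    ParamSpec("or_adult_judiciary_given_drug", "odds_ratio", 4.14, 1.2, 5.5),
    ParamSpec("or_judiciary_persistence", "odds_ratio", 227.0, 50.0, 250.0,
              note="judiciary interaction given one in the previous year"),
    ParamSpec("or_employment_given_graduated", "odds_ratio", 1.88, 1.5, 3.0),
    ParamSpec("or_employment_given_judiciary_last_year", "odds_ratio", 0.029, 0.005, 0.1),
    ParamSpec("or_drug_persistence", "odds_ratio", 47.6, 23.5, 571.0,
              note="drug abuse given drug abuse in the previous year"),
    ParamSpec("or_obesity_persistence", "odds_ratio", 331.0, math.nan, math.nan,
              note="obesity given obese in the previous year; no printed range"),
    # -- annual costs, 2015 $US
    ParamSpec("cost_drug_treatment", "cost_per_year", 1000.0, 500.0, 1500.0),
    ParamSpec("cost_drug_complication", "cost_per_year", 21483.0, 10742.0, 32225.0),
    ParamSpec("cost_diabetes_treatment", "cost_per_year", 9975.0, 4988.0, 14963.0),
    ParamSpec("cost_diabetes_complication", "cost_per_year", 1575.0, 788.0, 2363.0),
    ParamSpec("cost_obesity_treatment", "cost_per_year", 0.0, 0.0, 0.0),
    ParamSpec("cost_obesity_complication", "cost_per_year", 732.0, 366.0, 1098.0),
    ParamSpec("cost_incarceration", "cost_per_year", 28893.0, 14447.0, 43340.0),
    ParamSpec("cost_unemployment", "cost_per_year", 33160.0, 16580.0, 49740.0,
              note="opportunity cost of unemployment"),
    # -- program cost rows as printed in the inputs table (no ranges; the
    #    scenario costing uses the capacity/implementation breakdown instead)
    ParamSpec("pc_annual_cost_per_child", "program_cost", 500.0, 500.0, 500.0,
              note="ongoing annual cost per child; varied via scenario knobs only"),
    ParamSpec("pc_capacity_cost_per_school", "program_cost", 100000.0, 100000.0, 100000.0,
              note="capacity building per school; varied via scenario knobs only"),
    # -- utilities
    ParamSpec("utility_diabetes", "utility", 0.690, math.nan, math.nan),
    ParamSpec("utility_diabetes_complications", "utility", 0.350, math.nan, math.nan),
    ParamSpec("utility_drug", "utility", 0.670, math.nan, math.nan),
    ParamSpec("utility_drug_complications", "utility", 0.600, math.nan, math.nan),
    ParamSpec("utility_obese", "utility", 0.710, math.nan, math.nan),
    ParamSpec("utility_obesity_complications", "utility", 0.500, math.nan, math.nan),
    ParamSpec("utility_prison", "utility", 0.725, math.nan, math.nan),
    # -- excess-mortality hazard multipliers (not printed in the inputs
    #    table; calibration knobs, fixed unless overridden or calibrated)
    ParamSpec("mort_mult_cvd", "mortality_multiplier", 2.0, 2.0, 2.0,
              note="background-mortality multiplier while CVD present"),
    ParamSpec("mort_mult_diabetes", "mortality_multiplier", 1.5, 1.5, 1.5),
    ParamSpec("mort_mult_drug", "mortality_multiplier", 1.5, 1.5, 1.5),
]


def _fill_missing_ranges(spec: ParamSpec) -> ParamSpec:
    """Default a missing (NaN) range to +/-50% of the point value."""
    if not (math.isnan(spec.low) or math.isnan(spec.high)):
        return spec
    low = spec.value * 0.5
    high = spec.value * 1.5
    if spec.role == "utility":
        high = min(high, 1.0)
    logger.warning(
        "parameter %s has no printed range; defaulting to +/-50%% (%g, %g)",
        spec.name, low, high,
    )
    return replace(spec, low=low, high=high)


DEFAULT_MANIFEST: tuple[str, ...] = tuple(p.name for p in _RAW_DEFAULTS)


class ParamRegistry(Mapping[str, ParamSpec]):
    """Immutable-by-convention mapping of parameter name to :class:`ParamSpec`."""

    def __init__(self, specs: Iterator[ParamSpec] | list[ParamSpec]):
        self._specs: dict[str, ParamSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate parameter name: {spec.name}")
            self._specs[spec.name] = spec

    # Mapping interface -------------------------------------------------
    def __getitem__(self, name: str) -> ParamSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; valid names: {sorted(self._specs)}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParamRegistry):
            return NotImplemented
        return self._specs == other._specs

    # convenience --------------------------------------------------------
    def value(self, name: str) -> float:
        return self[name].value

    def band_value(self, name: str, age: int) -> float:
        return self[name].band_value(age)

    def override(self, name: str, value: float) -> "ParamRegistry":
        """Return a new registry with ``name``'s point value replaced.

        For age-banded parameters the override rescales every band by
        ``value / spec.value`` so a single scalar still steers the input.
        """
        spec = self[name]
        if spec.age_bands is not None and spec.value != 0:
            scale = value / spec.value
            bands = tuple(
                replace(b, value=b.value * scale) for b in spec.age_bands
            )
            new = replace(spec, value=value, age_bands=bands)
        else:
            new = replace(spec, value=value)
        specs = dict(self._specs)
        specs[name] = new
        return ParamRegistry(list(specs.values()))

    def replace_spec(self, spec: ParamSpec) -> "ParamRegistry":
        """Return a new registry with ``spec`` swapped in wholesale."""
        if spec.name not in self._specs:
            raise KeyError(f"unknown parameter {spec.name!r}")
        specs = dict(self._specs)
        specs[spec.name] = spec
        return ParamRegistry(list(specs.values()))

    def validate(self) -> list[str]:
        """Report every invariant violation (empty list means clean)."""
        problems: list[str] = []
        for spec in self._specs.values():
            rows = (
                [(spec.value, spec.low, spec.high, "")]
                if spec.age_bands is None
                else [
                    (b.value, b.low, b.high, f" [band {b.age_lo}-{b.age_hi}]")
                    for b in spec.age_bands
                ]
            )
            for value, low, high, where in rows:
                if low > high:
                    problems.append(f"{spec.name}{where}: low {low} > high {high}")
                elif not (low <= value <= high):
                    problems.append(
                        f"{spec.name}{where}: value {value} outside range [{low}, {high}]"
                    )
            if spec.role == "utility" and not (0.0 <= spec.value <= 1.0):
                problems.append(f"{spec.name}: utility {spec.value} outside [0, 1]")
            if spec.age_bands is not None:
                bands = sorted(spec.age_bands, key=lambda b: b.age_lo)
                for a, b in zip(bands, bands[1:]):
                    if b.age_lo != a.age_hi + 1:
                        problems.append(
                            f"{spec.name}: bands {a.age_lo}-{a.age_hi} and "
                            f"{b.age_lo}-{b.age_hi} do not tile contiguously"
                        )
        return problems

    # serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for spec in self._specs.values():
            if spec.age_bands is None:
                rows.append(
                    dict(name=spec.name, role=spec.role, value=spec.value,
                         low=spec.low, high=spec.high,
                         age_lo=None, age_hi=None, note=spec.note)
                )
            else:
                for band in spec.age_bands:
                    rows.append(
                        dict(name=spec.name, role=spec.role, value=band.value,
                             low=band.low, high=band.high,
                             age_lo=band.age_lo, age_hi=band.age_hi,
                             note=spec.note)
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ParamRegistry":
        specs: list[ParamSpec] = []
        for name, group in frame.groupby("name", sort=False):
            role = group["role"].iloc[0]
            if group["age_lo"].notna().any():
                bands = _bands(*[
                    (int(r.age_lo), int(r.age_hi), float(r.value),
                     float(r.low), float(r.high))
                    for r in group.itertuples()
                ])
                specs.append(ParamSpec(str(name), role, bands[0].value,
                                       bands[0].low, bands[0].high,
                                       age_bands=bands,
                                       note=str(group["note"].iloc[0] or "")))
            else:
                r = group.iloc[0]
                specs.append(ParamSpec(str(name), role, float(r["value"]),
                                       float(r["low"]), float(r["high"]),
                                       note=str(r["note"] or "")))
        return cls(specs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParamRegistry":
        return cls.from_frame(pd.read_csv(path, keep_default_na=True).fillna(
            {"note": ""}))


class ScenarioConfig(BaseModel):
    """Scenario-level knobs for one simulation run."""

    model_config = ConfigDict(extra="forbid")

    arm: Literal["intervention", "standard"] = "standard"
    n_individuals: int = Field(default=100_000, ge=1)
    seed: int = 0
    discount_rate: float = Field(default=0.05, ge=0.0, lt=1.0)
    entry_age: int = 5
    adult_age: int = 18
    max_age: int = 105
    school_size: int = Field(default=72, ge=1)
    pct_low_self_reg: float = Field(default=0.25, ge=0.0, le=1.0)
    capacity_cost: float = Field(default=200_000.0, ge=0.0)
    capacity_durability: int = Field(default=5, ge=2)
    annual_implementation_cost: float = Field(default=40_000.0, ge=0.0)
    life_table_source: str = "synthetic"
    gompertz_a: float = Field(default=1e-4, gt=0.0)
    gompertz_b: float = Field(default=0.085, ge=0.0)
    # structural switches (see docs/methods.md)
    obesity_pc_or_mode: Literal["multiply", "substitute"] = "multiply"
    cvd_or_mode: Literal["single", "multiplicative"] = "single"
    persistence_mode: Literal["odds_ratio", "probability"] = "odds_ratio"
    charge_childhood_judiciary: bool = False

    @field_validator("max_age")
    @classmethod
    def _max_age_sane(cls, v: int) -> int:
        if v <= 18:
            raise ValueError("max_age must exceed the adult entry age of 18")
        return v


def load_registry(source: str | Path | None = None) -> ParamRegistry:
    """Load the default registry, optionally applying a config file's overrides.

    With ``source=None`` the built-in defaults are returned. A path may point
    at a registry CSV export or a YAML/JSON config whose
    ``parameter_overrides`` section is applied on top of the defaults.
    """
    defaults = ParamRegistry([_fill_missing_ranges(s) for s in _RAW_DEFAULTS])
    if source is None:
        return defaults
    path = Path(source)
    if path.suffix == ".csv":
        reg = ParamRegistry.from_csv(path)
        missing = set(DEFAULT_MANIFEST) - set(reg)
        if missing:
            raise ValueError(f"registry file missing required parameters: {sorted(missing)}")
        return reg
    _, overrides = _read_config_file(path)
    reg = defaults
    for name, value in overrides.items():
        reg = reg.override(name, float(value))
    return reg


def _read_config_file(path: Path) -> tuple[dict, dict]:
    text = Path(path).read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(data) - {"scenario", "parameter_overrides"}
    if unknown:
        raise ValueError(
            f"unknown top-level config sections {sorted(unknown)}; "
            "expected 'scenario' and/or 'parameter_overrides'"
        )
    scenario = data.get("scenario") or {}
    overrides = data.get("parameter_overrides") or {}
    valid = set(DEFAULT_MANIFEST)
    bad = set(overrides) - valid
    if bad:
        raise ValueError(f"parameter_overrides for unknown parameters: {sorted(bad)}")
    return scenario, overrides


def load_config(path: str | Path) -> tuple[ScenarioConfig, ParamRegistry]:
    """Read a config file into a (ScenarioConfig, ParamRegistry) pair."""
    scenario, overrides = _read_config_file(Path(path))
    config = ScenarioConfig(**scenario)
    reg = load_registry()
    for name, value in overrides.items():
        reg = reg.override(name, float(value))
    return config, reg


# module-level functional aliases matching the operation names
def override(registry: ParamRegistry, name: str, value: float) -> ParamRegistry:
    """Return a copy of ``registry`` with one parameter's value changed."""
    return registry.override(name, value)


def validate_registry(registry: ParamRegistry) -> list[str]:
    """List every invariant violation in ``registry`` (empty when clean)."""
    return registry.validate()
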