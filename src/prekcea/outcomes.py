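"""Cost and utility accounting plus intervention costing.

Costs follow a societal perspective: annual treatment costs for each active
disease state (drug abuse, diabetes, obesity), annual complication costs for
each active sequela (psychiatric disorder for drug abuse; cardiovascular
disease attributed to diabetes when diabetic, otherwise to obesity when
obese), incarceration in a judiciary-interaction year, and the opportunity
cost of unemployment. Utilities use the minimum-across-conditions rule, with
unemployment carrying no utility penalty (its burden is counted in costs).

All dollar figures are 2015 $US; costs and QALYs are discounted to model
entry at the scenario discount rate; life years are counted undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .adulthood import AdultState
from .parameters import ParamRegistry
from .risk_math import discount_factor

__all__ = [
    "OutcomeAccumulator",
    "annual_cost",
    "annual_utility",
    "annual_cost_components",
    "annual_utility_from_flags",
    "accumulate",
    "program_cost_per_student",
]


@dataclass(frozen=True)
class OutcomeAccumulator:
    """Running discounted totals for one individual (or a mean)."""

    disc_cost: float = 0.0
    disc_qaly: float = 0.0
    life_years: float = 0.0


def annual_cost_components(obese, diabetes, drug, cvd, psych, judiciary,
                           employed, registry: ParamRegistry):
    """Annual cost from boolean state flags (scalars or arrays)."""
    r = registry.value
    obese = np.asarray(obese, dtype=bool)
    diabetes = np.asarray(diabetes, dtype=bool)
    cvd = np.asarray(cvd, dtype=bool)
    cost = (
        np.where(drug, r("cost_drug_treatment"), 0.0)
        + np.where(diabetes, r("cost_diabetes_treatment"), 0.0)
        + np.where(obese, r("cost_obesity_treatment"), 0.0)
        + np.where(psych, r("cost_drug_complication"), 0.0)
        + np.where(cvd & diabetes, r("cost_diabetes_complication"), 0.0)
        + np.where(cvd & ~diabetes & obese, r("cost_obesity_complication"), 0.0)
        + np.where(judiciary, r("cost_incarceration"), 0.0)
        + np.where(~np.asarray(employed, dtype=bool), r("cost_unemployment"), 0.0)
    )
    return float(cost) if np.ndim(cost) == 0 else cost


def annual_utility_from_flags(obese, diabetes, drug, cvd, psych, judiciary,
                              registry: ParamRegistry):
    """Annual utility from boolean state flags: minimum over active conditions.

    The cardiovascular sequela takes the diabetes-complication utility when
    diabetic, the obesity-complication utility when (only) obese; a
    cardiovascular flag with neither parent condition present carries no
    modeled utility penalty. Unemployment never reduces utility.
    """
    r = registry.value
    obese = np.asarray(obese, dtype=bool)
    diabetes = np.asarray(diabetes, dtype=bool)
    cvd = np.asarray(cvd, dtype=bool)
    one = np.ones(np.broadcast(obese, diabetes, cvd).shape or ())
    candidates = [
        np.where(obese, r("utility_obese"), 1.0),
        np.where(diabetes, r("utility_diabetes"), 1.0),
        np.where(drug, r("utility_drug"), 1.0),
        np.where(psych, r("utility_drug_complications"), 1.0),
        np.where(cvd & diabetes, r("utility_diabetes_complications"), 1.0),
        np.where(cvd & ~diabetes & obese, r("utility_obesity_complications"), 1.0),
        np.where(judiciary, r("utility_prison"), 1.0),
    ]
    util = one
    for c in candidates:
        util = np.minimum(util, c)
    return float(util) if np.ndim(util) == 0 else util


def annual_cost(state: AdultState, registry: ParamRegistry) -> float:
    """Annual cost of an alive adult state (2015 $US)."""
    if not state.alive:
        raise ValueError("dead states accrue no cost")
    return annual_cost_components(
        state.obese, state.diabetes, state.drug_abuse, state.cvd, state.psych,
        state.judiciary, state.employed, registry,
    )


def annual_utility(state: AdultState, registry: ParamRegistry) -> float:
    """Annual utility of an alive adult state, in [0, 1]."""
    if not state.alive:
        raise ValueError("dead states have no utility")
    return annual_utility_from_flags(
        state.obese, state.diabetes, state.drug_abuse, state.cvd, state.psych,
        state.judiciary, registry,
    )


def accumulate(acc: OutcomeAccumulator, cost: float, utility: float,
               years_since_entry: int, rate: float) -> OutcomeAccumulator:
    """Add one lived year's cost and utility, discounted to model entry."""
    if not 0.0 <= utility <= 1.0:
        raise ValueError("utility must lie in [0, 1]")
    d = discount_factor(rate, years_since_entry)
    return replace(
        acc,
        disc_cost=acc.disc_cost + cost * d,
        disc_qaly=acc.disc_qaly + utility * d,
        life_years=acc.life_years + 1.0,
    )


def program_cost_per_student(capacity_cost: float, durability: int,
                             annual_cost: float, students_per_year: int) -> float:
    """Amortized intervention cost per student.

    The capacity-building outlay covers implementation for the first two
    years; each remaining year of the investment's lifetime adds the annual
    implementation cost; the total is spread over every student served during
    the lifetime: ``(capacity + (durability - 2) * annual) /
    (students_per_year * durability)``. At the base configuration (200,000;
    5 yr; 40,000/yr; 72 students/yr) this is $320,000 over 360 students.
    """
    if durability < 2:
        raise ValueError("durability must be >= 2 (capacity covers the first 2 years)")
    if students_per_year < 1:
        raise ValueError("students_per_year must be >= 1")
    total = capacity_cost + (durability - 2) * annual_cost
    return total / (students_per_year * durability)
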