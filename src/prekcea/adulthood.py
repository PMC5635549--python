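"""Adult phase: one-year state transitions from age 18 until death.

Each adult year applies, in a fixed order: (1) a background-mortality draw,
with the life-table probability multiplied by excess-hazard factors for
active cardiovascular disease, diabetes and drug abuse (capped at 1); then
(2) obesity, (3) diabetes, (4) drug abuse, (5) cardiovascular disease,
(6) psychiatric disorder, and (7) judiciary interaction draws; finally
(8) employment, which is fixed from age 18 onward except for a re-draw with
a strong penalty in the year after a judiciary interaction. Diabetes,
cardiovascular disease and psychiatric disorder are absorbing; obesity, drug
abuse and judiciary interaction are re-drawn yearly with persistence odds
ratios conditioned on the previous year's status.

The over-60 obesity input (-0.002/yr as printed) is interpreted as net
remission: zero incidence plus an annual remission probability of 0.002
among the obese.

The transition-odds helpers accept scalars or arrays; the per-individual
``step_adult_year`` is the readable reference path and the cohort engine
applies the same helpers to whole arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .childhood import ChildProfile
from .lifetables import LifeTable
from .parameters import ParamRegistry
from .risk_math import adjust_odds, odds_to_prob

__all__ = [
    "AdultState",
    "ADULT_EVENT_ORDER",
    "init_adult_state",
    "step_adult_year",
    "mortality_multiplier",
    "obesity_transition_prob",
    "diabetes_odds",
    "drug_odds",
    "drug_transition_prob",
    "cvd_odds",
    "psych_odds",
    "judiciary_odds",
    "judiciary_transition_prob",
    "employment_odds",
]

# Draw order within a year; one uniform is consumed per entry every year so
# the stream stays aligned whatever the state (forced outcomes discard theirs).
ADULT_EVENT_ORDER: tuple[str, ...] = (
    "death", "obese", "diabetes", "drug_abuse", "cvd", "psych", "judiciary",
    "employment",
)


@dataclass(frozen=True)
class AdultState:
    """One adult's state at the start of a model year."""

    age: int
    alive: bool
    obese: bool
    diabetes: bool
    drug_abuse: bool
    cvd: bool
    psych: bool
    judiciary: bool
    judiciary_last_year: bool
    drug_abuse_last_year: bool
    obese_last_year: bool
    employed: bool
    graduated: bool


def init_adult_state(profile: ChildProfile, registry: ParamRegistry,
                     rng: np.random.Generator) -> AdultState:
    """Enter adulthood at 18, carrying childhood disease states.

    Employment is drawn once from the base employment odds, adjusted upward
    if the individual graduated from high school.
    """
    ors = [registry.value("or_employment_given_graduated")] if profile.graduated else []
    p_emp = odds_to_prob(adjust_odds(registry.value("odds_employment"), ors))
    employed = bool(rng.random() < p_emp)
    return AdultState(
        age=18,
        alive=True,
        obese=profile.obese,
        diabetes=profile.diabetes,
        drug_abuse=profile.drug_abuse,
        cvd=False,
        psych=False,
        judiciary=False,
        judiciary_last_year=False,
        drug_abuse_last_year=profile.drug_abuse,
        obese_last_year=profile.obese,
        employed=employed,
        graduated=profile.graduated,
    )


def mortality_multiplier(state_or_flags, registry: ParamRegistry):
    """Product of excess-mortality multipliers for the active conditions.

    Accepts an :class:`AdultState` or a ``(cvd, diabetes, drug)`` triple of
    bools/arrays; returns 1.0 for a healthy state.
    """
    if isinstance(state_or_flags, AdultState):
        cvd, diabetes, drug = (state_or_flags.cvd, state_or_flags.diabetes,
                               state_or_flags.drug_abuse)
    else:
        cvd, diabetes, drug = state_or_flags
    mult = (np.where(cvd, registry.value("mort_mult_cvd"), 1.0)
            * np.where(diabetes, registry.value("mort_mult_diabetes"), 1.0)
            * np.where(drug, registry.value("mort_mult_drug"), 1.0))
    return float(mult) if np.ndim(mult) == 0 else mult


# --- per-transition odds/probability helpers (scalar or array) -----------

def _persist_prob(adjusted_odds, persisting, mode: str):
    """Turn persistence-adjusted odds into a probability.

    ``mode="odds_ratio"`` converts via ``odds/(1+odds)`` like every other
    transition. ``mode="probability"`` reads the base-odds x persistence-OR
    product for persisting individuals as the intended annual retention
    probability itself (clipped at 1), matching the way the printed
    persistence ORs were back-calculated from retention/recidivism rates.
    """
    persisting = np.asarray(persisting, dtype=bool)
    if mode == "probability":
        return np.where(persisting,
                        np.clip(np.asarray(adjusted_odds, dtype=float), 0.0, 1.0),
                        odds_to_prob(np.where(persisting, 0.0, adjusted_odds)))
    return odds_to_prob(adjusted_odds)


def obesity_transition_prob(age: int, obese_last, registry: ParamRegistry,
                            mode: str = "odds_ratio"):
    """Probability of being obese this year given last year's status.

    For age bands with nonnegative incidence odds: incident odds for the
    previously non-obese, odds times the persistence OR for the previously
    obese. A negative band value v encodes zero incidence plus annual
    remission probability |v| among the obese.
    """
    band = registry.band_value("odds_adult_obesity_incidence", age)
    obese_last = np.asarray(obese_last, dtype=bool)
    if band < 0:
        p = np.where(obese_last, 1.0 + band, 0.0)  # stay-obese prob = 1 - |v|
    else:
        odds = np.where(
            obese_last,
            band * registry.value("or_obesity_persistence"),
            band,
        )
        p = _persist_prob(odds, obese_last, mode)
    return float(p) if np.ndim(p) == 0 else p


def diabetes_odds(obese_now, registry: ParamRegistry):
    """Annual diabetes incidence odds given current obesity (absorbing state)."""
    return (registry.value("odds_adult_diabetes_incidence")
            * np.where(obese_now, registry.value("or_adult_diabetes_given_obese"), 1.0))


def drug_odds(drug_last, registry: ParamRegistry):
    """Annual drug-abuse odds, with persistence OR if abusing last year."""
    return (registry.value("odds_adult_drug_incidence")
            * np.where(drug_last, registry.value("or_drug_persistence"), 1.0))


def drug_transition_prob(drug_last, registry: ParamRegistry,
                         mode: str = "odds_ratio"):
    """Annual probability of drug abuse given last year's status."""
    return _persist_prob(drug_odds(drug_last, registry), drug_last, mode)


def cvd_odds(age: int, obese_now, diabetes_now, registry: ParamRegistry,
             mode: str = "single"):
    """Annual cardiovascular-disease odds (absorbing sequela).

    ``mode="single"`` applies one common risk OR when obesity and/or
    diabetes is present (the two conditions carry the same CVD risk);
    ``mode="multiplicative"`` compounds the two ORs when both are present.
    """
    band = registry.band_value("odds_adult_cvd_incidence", age)
    if mode == "multiplicative":
        return (band
                * np.where(diabetes_now, registry.value("or_cvd_given_diabetes"), 1.0)
                * np.where(obese_now, registry.value("or_cvd_given_obese"), 1.0))
    either = np.asarray(obese_now, dtype=bool) | np.asarray(diabetes_now, dtype=bool)
    return band * np.where(either, registry.value("or_cvd_given_diabetes"), 1.0)


def psych_odds(drug_now, registry: ParamRegistry):
    """Annual psychiatric-disorder odds (absorbing sequela of drug abuse)."""
    return (registry.value("odds_adult_psych_incidence")
            * np.where(drug_now, registry.value("or_psych_given_drug"), 1.0))


def judiciary_odds(drug_now, judiciary_last, registry: ParamRegistry):
    """Annual judiciary-interaction odds with drug and recidivism ORs."""
    return (registry.value("odds_adult_judiciary_incidence")
            * np.where(drug_now, registry.value("or_adult_judiciary_given_drug"), 1.0)
            * np.where(judiciary_last, registry.value("or_judiciary_persistence"), 1.0))


def judiciary_transition_prob(drug_now, judiciary_last, registry: ParamRegistry,
                              mode: str = "odds_ratio"):
    """Annual probability of a judiciary interaction."""
    return _persist_prob(judiciary_odds(drug_now, judiciary_last, registry),
                         judiciary_last, mode)


def employment_odds(graduated, registry: ParamRegistry, *, after_judiciary: bool = True):
    """Employment odds for the post-judiciary re-draw (or the age-18 draw)."""
    odds = (registry.value("odds_employment")
            * np.where(graduated, registry.value("or_employment_given_graduated"), 1.0))
    if after_judiciary:
        odds = odds * registry.value("or_employment_given_judiciary_last_year")
    return odds


def step_adult_year(state: AdultState, registry: ParamRegistry,
                    lifetable: LifeTable, rng: np.random.Generator,
                    *, cvd_or_mode: str = "single",
                    persistence_mode: str = "odds_ratio") -> AdultState:
    """Advance one adult one model year.

    Consumes exactly eight uniforms in :data:`ADULT_EVENT_ORDER` regardless
    of the state, so random streams stay aligned across scenarios. Raises
    ``ValueError`` when stepping a dead state.
    """
    if not state.alive:
        raise ValueError("cannot step a dead state")
    u = rng.random(len(ADULT_EVENT_ORDER))

    q = min(1.0, lifetable.q(state.age) * mortality_multiplier(state, registry))
    if u[0] < q:
        return replace(state, alive=False)

    obese = bool(u[1] < obesity_transition_prob(state.age, state.obese_last_year,
                                                registry, mode=persistence_mode))
    diabetes = state.diabetes or bool(
        u[2] < odds_to_prob(diabetes_odds(obese, registry)))
    drug = bool(u[3] < drug_transition_prob(state.drug_abuse_last_year, registry,
                                            mode=persistence_mode))
    cvd = state.cvd or bool(
        u[4] < odds_to_prob(cvd_odds(state.age, obese, diabetes, registry,
                                     mode=cvd_or_mode)))
    psych = state.psych or bool(u[5] < odds_to_prob(psych_odds(drug, registry)))
    judiciary = bool(
        u[6] < judiciary_transition_prob(drug, state.judiciary_last_year, registry,
                                         mode=persistence_mode))
    employed = state.employed
    if state.judiciary_last_year:
        employed = bool(u[7] < odds_to_prob(
            employment_odds(state.graduated, registry)))

    return replace(
        state,
        age=state.age + 1,
        obese=obese,
        diabetes=diabetes,
        drug_abuse=drug,
        cvd=cvd,
        psych=psych,
        judiciary=judiciary,
        judiciary_last_year=judiciary,
        drug_abuse_last_year=drug,
        obese_last_year=obese,
        employed=employed,
    )
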