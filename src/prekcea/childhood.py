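"""Childhood phase: one-shot sampling of the eight correlated binary outcomes.

The childhood phase (entry at about age 5 through age 18) is a single cycle:
each outcome is drawn once, in a fixed order that respects the influence
structure — low self-regulation -> behavior problems -> academic proficiency
-> drug abuse -> obesity -> diabetes -> judiciary interaction -> graduation.
Each event's odds are the printed base odds adjusted by the odds ratios of
exactly the events that influence it (and by the intervention's effect odds
ratios in the intervention arm).

``child_event_odds`` does the odds algebra and accepts scalars or NumPy
arrays, so the same code backs both the per-individual sampler here and the
vectorized cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .parameters import ParamRegistry
from .risk_math import odds_to_prob

__all__ = ["ChildProfile", "CHILD_EVENT_ORDER", "child_event_odds", "draw_child_profile"]

Arm = Literal["intervention", "standard"]

# Sampling order: a topological order of the influence diagram; each event
# conditions only on events earlier in this list.
CHILD_EVENT_ORDER: tuple[str, ...] = (
    "low_self_reg",
    "behavior_problems",
    "academic_proficient",
    "drug_abuse",
    "obese",
    "diabetes",
    "judiciary",
    "graduated",
)


@dataclass(frozen=True)
class ChildProfile:
    """The eight binary childhood outcomes, fully determined by the sampler."""

    arm: Arm
    low_self_reg: bool
    behavior_problems: bool
    academic_proficient: bool
    drug_abuse: bool
    obese: bool
    diabetes: bool
    judiciary: bool
    graduated: bool


def _where(flag, ratio: float):
    """OR applied where ``flag`` holds (scalar bool or bool array)."""
    return np.where(flag, ratio, 1.0)


def child_event_odds(
    event: str,
    partial: Mapping[str, object],
    registry: ParamRegistry,
    *,
    intervention,
    obesity_pc_or_mode: str = "multiply",
):
    """Adjusted odds of ``event`` given the upstream events in ``partial``.

    ``partial`` maps upstream event names to bools (or bool arrays);
    ``intervention`` is a bool (or bool array) marking the intervention arm.
    Raises ``KeyError`` for an unknown event and for an unset upstream field.

    ``obesity_pc_or_mode`` selects how the intervention's obesity effect in
    the low-self-regulation subgroup composes with the subgroup risk itself:
    ``"multiply"`` applies both odds ratios, ``"substitute"`` replaces the
    risk OR with the intervention OR.
    """
    r = registry.value
    arm = np.asarray(intervention, dtype=bool)

    def need(name: str):
        if name not in partial or partial[name] is None:
            raise KeyError(f"event {event!r} requires upstream field {name!r}")
        return np.asarray(partial[name], dtype=bool)

    if event == "low_self_reg":
        odds = np.broadcast_to(np.asarray(r("odds_child_low_self_reg")), arm.shape).copy() \
            if arm.ndim else r("odds_child_low_self_reg")
    elif event == "behavior_problems":
        odds = (r("odds_child_behavior")
                * _where(need("low_self_reg"), r("or_behavior_given_low_self_reg"))
                * _where(arm, r("or_pc_behavior")))
    elif event == "academic_proficient":
        odds = (r("odds_child_academic")
                * _where(arm, r("or_pc_academic"))
                * _where(need("behavior_problems"), r("or_academic_given_behavior")))
    elif event == "drug_abuse":
        odds = (r("odds_child_drug")
                * _where(need("behavior_problems"), r("or_child_drug_given_behavior")))
    elif event == "obese":
        lsr = need("low_self_reg")
        base = r("odds_child_obese")
        risk = r("or_obese_given_low_self_reg")
        pc_lsr = r("or_pc_obese_low_self_reg")
        pc_no_lsr = r("or_pc_obese_no_low_self_reg")
        if obesity_pc_or_mode == "substitute":
            lsr_factor = np.where(lsr & arm, pc_lsr, np.where(lsr, risk, 1.0))
            odds = base * lsr_factor * _where(~lsr & arm, pc_no_lsr)
        else:
            odds = (base * _where(lsr, risk)
                    * _where(lsr & arm, pc_lsr)
                    * _where(~lsr & arm, pc_no_lsr))
    elif event == "diabetes":
        odds = (r("odds_child_diabetes")
                * _where(need("obese"), r("or_child_diabetes_given_obese")))
    elif event == "judiciary":
        odds = (r("odds_child_judiciary")
                * _where(need("drug_abuse"), r("or_child_judiciary_given_drug"))
                * _where(need("behavior_problems"), r("or_child_judiciary_given_behavior")))
    elif event == "graduated":
        odds = (r("odds_graduate_hs")
                * _where(need("academic_proficient"), r("or_graduate_given_academic"))
                * _where(need("drug_abuse"), r("or_graduate_given_drug"))
                * _where(need("behavior_problems"), r("or_graduate_given_behavior")))
    else:
        raise KeyError(
            f"unknown childhood event {event!r}; valid events: {CHILD_EVENT_ORDER}"
        )
    out = np.asarray(odds, dtype=float)
    return float(out) if out.ndim == 0 else out


def draw_child_profile(
    arm: Arm,
    registry: ParamRegistry,
    pct_low_self_reg: float,
    rng: np.random.Generator,
    *,
    obesity_pc_or_mode: str = "multiply",
) -> ChildProfile:
    """Sample one complete childhood profile.

    Low self-regulation is drawn from the scenario prevalence
    ``pct_low_self_reg``; every other event is a Bernoulli draw on its
    adjusted odds converted via ``odds/(1+odds)``, in the fixed order of
    ``CHILD_EVENT_ORDER``. One uniform variate is consumed per event so the
    draw sequence is stable across parameter settings.
    """
    intervention = arm == "intervention"
    flags: dict[str, bool] = {}
    for event in CHILD_EVENT_ORDER:
        u = rng.random()
        if event == "low_self_reg":
            p = pct_low_self_reg
        else:
            odds = child_event_odds(
                event, flags, registry,
                intervention=intervention,
                obesity_pc_or_mode=obesity_pc_or_mode,
            )
            p = odds_to_prob(odds)
        flags[event] = bool(u < p)
    return ChildProfile(arm=arm, **{
        "low_self_reg": flags["low_self_reg"],
        "behavior_problems": flags["behavior_problems"],
        "academic_proficient": flags["academic_proficient"],
        "drug_abuse": flags["drug_abuse"],
        "obese": flags["obese"],
        "diabetes": flags["diabetes"],
        "judiciary": flags["judiciary"],
        "graduated": flags["graduated"],
    })
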