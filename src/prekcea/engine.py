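"""Two-arm cohort microsimulation, sensitivity analysis and threshold search.

The engine simulates whole cohorts as NumPy arrays but reproduces exactly the
per-individual model defined in :mod:`childhood` and :mod:`adulthood`: every
decision (each childhood event, and each of the eight adult events in every
model year) has its own random stream, and individual ``i`` always consumes
the ``i``-th variate of each stream. Consequences:

* results for individual ``i`` do not depend on cohort size or batching;
* the two arms run on common random numbers (CRN) — identical streams — so a
  null intervention produces bit-identical trajectories and paired
  differences are variance-reduced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np

from .adulthood import (
    cvd_odds,
    diabetes_odds,
    drug_transition_prob,
    employment_odds,
    judiciary_transition_prob,
    mortality_multiplier,
    obesity_transition_prob,
    psych_odds,
)
from .childhood import CHILD_EVENT_ORDER, child_event_odds
from .lifetables import LifeTable, load_life_table, make_gompertz_lifetable
from .outcomes import (
    annual_cost_components,
    annual_utility_from_flags,
    program_cost_per_student,
)
from .parameters import ParamRegistry, ScenarioConfig
from .risk_math import discount_factor, odds_to_prob

logger = logging.getLogger(__name__)

__all__ = [
    "ArmResult",
    "ComparisonResult",
    "TornadoEntry",
    "lifetable_for",
    "run_arm",
    "compare_arms",
    "one_way_sa",
    "threshold_search",
    "calibrate_mortality",
]

# stream-id layout: childhood events 0..7, employment-at-18 draw 8,
# adult year blocks of 8 starting at 16
_EMPLOYMENT_STAGE = 8
_ADULT_STAGE_BASE = 16
_ADULT_EVENTS = 8


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & (2**63 - 1), stage]))


def _stage_uniforms(seed: int, stage: int, n: int) -> np.ndarray:
    return _stage_rng(seed, stage).random(n)


@dataclass(frozen=True)
class ArmResult:
    """Cohort means and Monte-Carlo standard errors for one arm."""

    mean_disc_cost: float
    mean_disc_qaly: float
    mean_life_years: float
    se_cost: float
    se_qaly: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    """Paired intervention-minus-standard contrasts under CRN.

    ``delta_cost`` includes the per-student program cost charged to the
    intervention arm at entry; negative values mean the intervention saves
    money.
    """

    delta_cost: float
    delta_qaly: float
    delta_life_years: float
    se_delta_cost: float
    se_delta_qaly: float
    intervention: ArmResult
    standard: ArmResult
    cost_per_student: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    param: str
    low: float
    high: float
    outcome_at_low: float
    outcome_at_high: float
    base_outcome: float
    outcome: str

    @property
    def spread(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def lifetable_for(config: ScenarioConfig) -> LifeTable:
    """Resolve the scenario's life table (synthetic Gompertz or CSV path)."""
    if config.life_table_source == "synthetic":
        return make_gompertz_lifetable(config.gompertz_a, config.gompertz_b,
                                       config.max_age)
    return load_life_table(config.life_table_source)


# --- cohort phases -------------------------------------------------------

def _childhood_phase(config: ScenarioConfig, registry: ParamRegistry,
                     arm: str, seed: int) -> dict[str, np.ndarray]:
    """Vectorized childhood sampling; returns the profile flag arrays."""
    n = config.n_individuals
    intervention = arm == "intervention"
    flags: dict[str, np.ndarray] = {}
    for stage, event in enumerate(CHILD_EVENT_ORDER):
        u = _stage_uniforms(seed, stage, n)
        if event == "low_self_reg":
            p = np.full(n, config.pct_low_self_reg)
        else:
            odds = child_event_odds(
                event, flags, registry,
                intervention=np.full(n, intervention),
                obesity_pc_or_mode=config.obesity_pc_or_mode,
            )
            p = odds_to_prob(np.asarray(odds, dtype=float))
        flags[event] = u < p
    return flags


def _adult_phase(config: ScenarioConfig, registry: ParamRegistry,
                 lifetable: LifeTable, seed: int,
                 init: dict[str, np.ndarray],
                 return_state: bool = False) -> dict[str, np.ndarray]:
    """Run the annual adult loop from the adult entry age to max_age.

    ``init`` must contain boolean arrays ``graduated, obese, diabetes,
    drug_abuse, employed`` (states at entry). Returns per-individual
    discounted cost, discounted QALYs, and life years accrued in adulthood;
    with ``return_state=True`` the final state-flag arrays are included.
    """
    n = next(iter(init.values())).size
    rate = config.discount_rate
    alive = np.ones(n, dtype=bool)
    graduated = init["graduated"].copy()
    diabetes = init["diabetes"].copy()
    cvd = np.zeros(n, dtype=bool)
    psych = np.zeros(n, dtype=bool)
    obese_last = init["obese"].copy()
    drug_last = init["drug_abuse"].copy()
    jud_last = np.zeros(n, dtype=bool)
    employed = init["employed"].copy()

    disc_cost = np.zeros(n)
    disc_qaly = np.zeros(n)
    life_years = np.zeros(n)

    for age in range(config.adult_age, config.max_age + 1):
        if not alive.any():
            break
        block = _ADULT_STAGE_BASE + (age - config.adult_age) * _ADULT_EVENTS
        u = [_stage_uniforms(seed, block + k, n) for k in range(_ADULT_EVENTS)]

        q_bg = lifetable.q(age) if age <= lifetable.max_age else 1.0
        p_death = np.minimum(
            1.0, q_bg * mortality_multiplier((cvd, diabetes, drug_last), registry))
        alive = alive & ~(u[0] < p_death)

        obese = u[1] < obesity_transition_prob(age, obese_last, registry,
                                               mode=config.persistence_mode)
        diabetes_new = diabetes | (u[2] < odds_to_prob(diabetes_odds(obese, registry)))
        drug = u[3] < drug_transition_prob(drug_last, registry,
                                           mode=config.persistence_mode)
        cvd_new = cvd | (u[4] < odds_to_prob(
            cvd_odds(age, obese, diabetes_new, registry, mode=config.cvd_or_mode)))
        psych_new = psych | (u[5] < odds_to_prob(psych_odds(drug, registry)))
        jud = u[6] < judiciary_transition_prob(drug, jud_last, registry,
                                               mode=config.persistence_mode)
        emp_redraw = u[7] < odds_to_prob(employment_odds(graduated, registry))
        employed_new = np.where(jud_last, emp_redraw, employed)

        # only survivors' states advance; the dead keep their final state
        obese = np.where(alive, obese, obese_last)
        diabetes = np.where(alive, diabetes_new, diabetes)
        drug = np.where(alive, drug, drug_last)
        cvd = np.where(alive, cvd_new, cvd)
        psych = np.where(alive, psych_new, psych)
        jud = np.where(alive, jud, jud_last)
        employed = np.where(alive, employed_new, employed)

        d = discount_factor(rate, age - config.entry_age)
        cost = annual_cost_components(obese, diabetes, drug, cvd, psych, jud,
                                      employed, registry)
        util = annual_utility_from_flags(obese, diabetes, drug, cvd, psych,
                                         jud, registry)
        disc_cost += np.where(alive, cost, 0.0) * d
        disc_qaly += np.where(alive, util, 0.0) * d
        life_years += alive

        obese_last, drug_last, jud_last = obese, drug, jud
        if age == config.max_age:
            alive[:] = False

    out = {"disc_cost": disc_cost, "disc_qaly": disc_qaly,
           "life_years": life_years}
    if return_state:
        out.update({"obese": obese_last, "diabetes": diabetes, "cvd": cvd,
                    "psych": psych, "drug_abuse": drug_last,
                    "judiciary": jud_last, "employed": employed,
                    "alive": alive})
    return out


def _simulate_arm_arrays(config: ScenarioConfig, registry: ParamRegistry,
                         lifetable: LifeTable, arm: str,
                         seed: int) -> dict[str, np.ndarray]:
    """Per-individual discounted cost/QALY/life-year arrays for one arm."""
    n = config.n_individuals
    rate = config.discount_rate
    child_years = config.adult_age - config.entry_age
    profile = _childhood_phase(config, registry, arm, seed)

    # childhood: full health in both arms; 13 discounted years at utility 1
    d_child = discount_factor(rate, np.arange(child_years))
    disc_qaly = np.full(n, float(np.sum(d_child)))
    disc_cost = np.zeros(n)
    life_years = np.full(n, float(child_years))
    if config.charge_childhood_judiciary:
        # one incarceration-year charged at mid-childhood
        d_mid = discount_factor(rate, child_years // 2)
        disc_cost += np.where(profile["judiciary"],
                              registry.value("cost_incarceration") * d_mid, 0.0)

    u_emp = _stage_uniforms(seed, _EMPLOYMENT_STAGE, n)
    p_emp = odds_to_prob(employment_odds(profile["graduated"], registry,
                                         after_judiciary=False))
    employed = u_emp < p_emp

    adult = _adult_phase(config, registry, lifetable, seed, {
        "graduated": profile["graduated"],
        "obese": profile["obese"],
        "diabetes": profile["diabetes"],
        "drug_abuse": profile["drug_abuse"],
        "employed": employed,
    })
    return {
        "disc_cost": disc_cost + adult["disc_cost"],
        "disc_qaly": disc_qaly + adult["disc_qaly"],
        "life_years": life_years + adult["life_years"],
    }


def _summarize(arrays: dict[str, np.ndarray]) -> ArmResult:
    n = arrays["disc_cost"].size
    return ArmResult(
        mean_disc_cost=float(arrays["disc_cost"].mean()),
        mean_disc_qaly=float(arrays["disc_qaly"].mean()),
        mean_life_years=float(arrays["life_years"].mean()),
        se_cost=float(arrays["disc_cost"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(arrays["disc_qaly"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
    )


def run_arm(config: ScenarioConfig, registry: ParamRegistry,
            lifetable: LifeTable | None = None,
            seed: int | None = None) -> ArmResult:
    """Simulate one arm and return cohort means with Monte-Carlo SEs.

    The arm simulated is ``config.arm``; program costs are *not* charged
    here (they belong to the comparison).
    """
    lifetable = lifetable if lifetable is not None else lifetable_for(config)
    seed = config.seed if seed is None else seed
    return _summarize(
        _simulate_arm_arrays(config, registry, lifetable, config.arm, seed))


def compare_arms(config: ScenarioConfig, registry: ParamRegistry,
                 lifetable: LifeTable | None = None,
                 seed: int | None = None,
                 cost_per_student: float | None = None) -> ComparisonResult:
    """Run both arms on common random numbers and contrast them.

    The intervention arm is charged the amortized per-student program cost
    once at model entry (undiscounted). ``cost_per_student`` overrides the
    cost computed from the scenario's program-costing knobs (used by
    threshold analysis).
    """
    lifetable = lifetable if lifetable is not None else lifetable_for(config)
    seed = config.seed if seed is None else seed
    if cost_per_student is None:
        cost_per_student = program_cost_per_student(
            config.capacity_cost, config.capacity_durability,
            config.annual_implementation_cost, config.school_size)

    std = _simulate_arm_arrays(config, registry, lifetable, "standard", seed)
    itv = _simulate_arm_arrays(config, registry, lifetable, "intervention", seed)
    itv["disc_cost"] = itv["disc_cost"] + cost_per_student

    n = config.n_individuals
    d_cost = itv["disc_cost"] - std["disc_cost"]
    d_qaly = itv["disc_qaly"] - std["disc_qaly"]
    d_ly = itv["life_years"] - std["life_years"]
    return ComparisonResult(
        delta_cost=float(d_cost.mean()),
        delta_qaly=float(d_qaly.mean()),
        delta_life_years=float(d_ly.mean()),
        se_delta_cost=float(d_cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_delta_qaly=float(d_qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        intervention=_summarize(itv),
        standard=_summarize(std),
        cost_per_student=float(cost_per_student),
        seed=seed,
    )


# --- sensitivity analysis ------------------------------------------------

def _registry_at_bound(registry: ParamRegistry, name: str, which: str) -> ParamRegistry:
    """Registry with ``name`` pinned at its lower or upper plausible bound."""
    from dataclasses import replace as _replace

    spec = registry[name]
    if spec.age_bands is not None:
        bands = tuple(
            _replace(b, value=(b.low if which == "low" else b.high))
            for b in spec.age_bands
        )
        new = _replace(spec, value=bands[0].value, age_bands=bands)
        return registry.replace_spec(new)
    bound = spec.low if which == "low" else spec.high
    return registry.override(name, bound)


def _param_bounds(registry: ParamRegistry, name: str) -> tuple[float, float]:
    spec = registry[name]
    if spec.age_bands is not None:
        return (min(b.low for b in spec.age_bands),
                max(b.high for b in spec.age_bands))
    return spec.low, spec.high


def _has_range(registry: ParamRegistry, name: str) -> bool:
    spec = registry[name]
    if spec.age_bands is not None:
        return any(b.low != b.high for b in spec.age_bands)
    return spec.low != spec.high


def one_way_sa(config: ScenarioConfig, registry: ParamRegistry,
               lifetable: LifeTable | None = None,
               params: Sequence[str] | None = None,
               outcome: str = "delta_cost",
               seed: int | None = None) -> list[TornadoEntry]:
    """One-way sensitivity analysis: rerun the comparison at each parameter's
    plausible bounds (same seed, common random numbers), others held at base.

    With ``params=None`` every registry parameter with a non-degenerate range
    is analysed. An explicitly requested parameter without a range still
    yields a (zero-spread) entry, with a warning. Entries carry the chosen
    outcome (``delta_cost`` or ``delta_qaly``) and can be sorted by
    ``spread`` for a tornado diagram.
    """
    if outcome not in ("delta_cost", "delta_qaly"):
        raise ValueError("outcome must be 'delta_cost' or 'delta_qaly'")
    lifetable = lifetable if lifetable is not None else lifetable_for(config)
    seed = config.seed if seed is None else seed
    if params is None:
        params = [name for name in registry if _has_range(registry, name)]

    base = getattr(compare_arms(config, registry, lifetable, seed), outcome)
    entries: list[TornadoEntry] = []
    for name in params:
        if not _has_range(registry, name):
            warnings.warn(f"parameter {name!r} has a degenerate plausible range")
        low, high = _param_bounds(registry, name)
        at_low = getattr(
            compare_arms(config, _registry_at_bound(registry, name, "low"),
                         lifetable, seed), outcome)
        at_high = getattr(
            compare_arms(config, _registry_at_bound(registry, name, "high"),
                         lifetable, seed), outcome)
        entries.append(TornadoEntry(
            param=name, low=low, high=high,
            outcome_at_low=at_low, outcome_at_high=at_high,
            base_outcome=base, outcome=outcome,
        ))
    return entries


# --- threshold analysis --------------------------------------------------

_SCENARIO_THRESHOLD_PARAMS = ("cost_per_student", "school_size",
                              "pct_low_self_reg", "capacity_durability")


def threshold_search(config: ScenarioConfig, registry: ParamRegistry,
                     lifetable: LifeTable | None = None,
                     param: str = "cost_per_student",
                     bracket: tuple[float, float] = (0.0, 10_000.0),
                     seed: int | None = None,
                     criterion: str = "delta_cost",
                     rel_tol: float = 1e-3) -> float:
    """Find the value of ``param`` at which the criterion changes sign.

    Bisection on the CRN-smoothed criterion (fixed seed, so the objective is
    deterministic). ``param`` may be a registry name or one of the scenario
    knobs ``cost_per_student``, ``school_size``, ``pct_low_self_reg``,
    ``capacity_durability``. ``school_size`` and ``capacity_durability`` are
    integer-valued: the search scans the bracket and returns the smallest
    value at which the criterion is negative (cost saving).

    For ``cost_per_student`` the program charge enters the contrast as an
    exact additive constant under CRN, so the gross contrast is computed once
    and the threshold solved from it — identical to bisecting the full model.
    """
    lifetable = lifetable if lifetable is not None else lifetable_for(config)
    seed = config.seed if seed is None else seed
    if criterion != "delta_cost":
        raise ValueError("only the delta_cost = 0 criterion is supported")

    if param in ("cost_per_student", "school_size"):
        gross = compare_arms(config, registry, lifetable, seed,
                             cost_per_student=0.0).delta_cost

        if param == "cost_per_student":
            f = lambda x: gross + x
        else:
            def f(s):
                return gross + program_cost_per_student(
                    config.capacity_cost, config.capacity_durability,
                    config.annual_implementation_cost, int(round(s)))
            lo_i, hi_i = int(np.ceil(bracket[0])), int(np.floor(bracket[1]))
            lo_i = max(lo_i, 1)
            values = [(s, f(s)) for s in range(lo_i, hi_i + 1)]
            negatives = [s for s, v in values if v < 0]
            if not negatives:
                raise ValueError(
                    f"criterion does not change sign over school sizes "
                    f"{lo_i}..{hi_i}: f({lo_i})={values[0][1]:.2f}, "
                    f"f({hi_i})={values[-1][1]:.2f}")
            return float(min(negatives))
    elif param == "capacity_durability":
        def f(dur):
            cps = program_cost_per_student(
                config.capacity_cost, int(round(dur)),
                config.annual_implementation_cost, config.school_size)
            return compare_arms(config, registry, lifetable, seed,
                                cost_per_student=cps).delta_cost
        lo_i, hi_i = int(np.ceil(bracket[0])), int(np.floor(bracket[1]))
        lo_i = max(lo_i, 2)
        for dur in range(lo_i, hi_i + 1):
            if f(dur) < 0:
                return float(dur)
        raise ValueError(f"criterion stays nonnegative over durabilities {lo_i}..{hi_i}")
    elif param == "pct_low_self_reg":
        def f(x):
            cfg = config.model_copy(update={"pct_low_self_reg": float(x)})
            return compare_arms(cfg, registry, lifetable, seed).delta_cost
    else:
        def f(x):
            return compare_arms(config, registry.override(param, float(x)),
                                lifetable, seed).delta_cost

    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"criterion does not change sign over bracket ({lo}, {hi}): "
            f"f(lo)={f_lo:.4f}, f(hi)={f_hi:.4f}")
    tol = rel_tol * (hi - lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid == 0.0:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


# --- mortality calibration ----------------------------------------------

def simulate_obese_adult_life_expectancy(
        registry: ParamRegistry, lifetable: LifeTable,
        config: ScenarioConfig | None = None,
        n: int = 20_000, seed: int = 0) -> float:
    """Mean remaining life years of 18-year-olds entering adulthood obese."""
    config = config or ScenarioConfig()
    cfg = config.model_copy(update={"n_individuals": n})
    init = {
        "graduated": np.zeros(n, dtype=bool),
        "obese": np.ones(n, dtype=bool),
        "diabetes": np.zeros(n, dtype=bool),
        "drug_abuse": np.zeros(n, dtype=bool),
        "employed": np.ones(n, dtype=bool),
    }
    out = _adult_phase(cfg, registry, lifetable, seed, init)
    return float(out["life_years"].mean())


def calibrate_mortality(registry: ParamRegistry, lifetable: LifeTable,
                        target_life_expectancy: float = 60.1,
                        n: int = 20_000, seed: int = 0,
                        scale_bracket: tuple[float, float] = (0.1, 10.0),
                        tol: float = 0.05) -> ParamRegistry:
    """Scale the excess-mortality multipliers to hit a validation target.

    The three condition multipliers are unprinted model inputs; this scales
    their excess parts, ``m -> 1 + scale * (m - 1)``, by bisection until the
    simulated remaining life expectancy of an 18-year-old entering adulthood
    obese matches ``target_life_expectancy`` (within ``tol`` years, CRN-fixed
    seed). Returns the calibrated registry.
    """
    names = ("mort_mult_cvd", "mort_mult_diabetes", "mort_mult_drug")
    base = {name: registry.value(name) for name in names}

    def scaled_registry(scale: float) -> ParamRegistry:
        reg = registry
        for name, m in base.items():
            reg = reg.override(name, 1.0 + scale * (m - 1.0))
        return reg

    def le(scale: float) -> float:
        return simulate_obese_adult_life_expectancy(
            scaled_registry(scale), lifetable, n=n, seed=seed)

    lo, hi = scale_bracket
    le_lo, le_hi = le(lo), le(hi)  # le is decreasing in scale
    if not (le_hi <= target_life_expectancy <= le_lo):
        logger.warning(
            "target life expectancy %.1f outside achievable range [%.1f, %.1f]; "
            "returning nearest endpoint", target_life_expectancy, le_hi, le_lo)
        return scaled_registry(lo if abs(le_lo - target_life_expectancy)
                               < abs(le_hi - target_life_expectancy) else hi)
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        le_mid = le(mid)
        if abs(le_mid - target_life_expectancy) <= tol:
            return scaled_registry(mid)
        if le_mid > target_life_expectancy:
            lo = mid
        else:
            hi = mid
    return scaled_registry(0.5 * (lo + hi))
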