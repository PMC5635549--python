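# Methods

## Model overview

`prekcea` is a state-transition microsimulation of a cohort of children who
either receive a family-centered enhancement to pre-kindergarten or standard
pre-k programming. Each simulated individual enters at about age 5, passes
through a single-cycle childhood phase ending at 18, then through annual
adult cycles until death, accumulating three outcomes: discounted cost
(societal perspective, 2015 $US), discounted QALYs, and undiscounted life
years. The comparison of interest is the paired intervention-minus-standard
contrast of the cohort means.

All event likelihoods are carried as odds; conditioning is multiplicative
on the odds scale (the standard logistic-model convention, and the only
order-independent choice when several conditions apply at once); draws use
p = odds/(1 + odds).

## Childhood phase

Childhood is one Markov cycle of 13 years with eight binary outcomes,
sampled in a fixed topological order of the influence structure:

| event | base odds | adjusted by |
|---|---|---|
| low self-regulation | scenario prevalence (0.25) | — |
| behavior problems | 0.275 | ×3.8 low self-reg; ×0.59 intervention |
| academic proficiency | 1.35 | ×1.52 intervention; ×0.229 behavior |
| drug abuse | 0.13 | ×3.8 behavior |
| obesity | 0.146 | ×3.846 low self-reg; ×0.26 low self-reg ∧ intervention; ×1.0 ¬low self-reg ∧ intervention |
| diabetes | 0.001 | ×5.1 obesity |
| judiciary interaction | 0.099 | ×5.7 drug; ×2.925 behavior |
| graduation | 2.125 | ×1.335 academic; ×0.699 drug; ×0.18 behavior |

Any topological order gives the same joint distribution since each event
conditions only on its parents; one order is fixed for reproducibility.

Two childhood design points were genuinely open:

- **Obesity effect composition.** The intervention's obesity odds ratio of
  0.26 was estimated within the low-self-regulation subgroup as an
  intervention-vs-control contrast, so by default it *multiplies* the
  subgroup risk OR (0.146 × 3.846 × 0.26 ≈ 0.146 — the intervention
  approximately cancels the subgroup's excess risk). The alternative
  reading, substituting 0.26 for 3.846, is available as
  `obesity_pc_or_mode="substitute"`.
- **Childhood accounting.** Health sequelae are assumed to begin only in
  adulthood, so childhood contributes 13 discounted full-health years and no
  disease costs in both arms. A switch (`charge_childhood_judiciary`,
  default off) optionally charges one discounted incarceration-year, at the
  childhood midpoint, for a childhood judiciary interaction; the source
  model's treatment of that cost is not recoverable, and leaving it off is
  the conservative (benefit-understating) choice.

## Adult phase

Adults are described by five attributes (obesity, diabetes, drug abuse,
judiciary interaction, employment) plus two absorbing sequela flags
(cardiovascular disease for obesity/diabetes; psychiatric disorder for drug
abuse). Rather than enumerating the joint Markov state space explicitly, the
microsimulation tracks the attributes directly; the state space is emergent
bookkeeping.

Each year applies, in fixed order: death draw; obesity; diabetes; drug
abuse; cardiovascular disease; psychiatric disorder; judiciary interaction;
employment. Death first means decedents accrue no cost or utility in their
death year. Annual inputs:

- **Obesity**: age-banded incidence odds (18–39: 0.003; 40–59: 0.005), with
  persistence OR 331 applied when obese the previous year. The printed
  over-60 value of −0.002/yr is interpreted as *net remission*: zero
  incidence plus annual remission probability 0.002 among the obese — the
  only reading that keeps probabilities valid.
- **Diabetes** (absorbing): odds 0.0069/yr, ×7.37 while obese.
- **Drug abuse**: odds 0.007/yr, persistence OR 47.6.
- **Cardiovascular disease** (absorbing): six age-banded odds
  (0.004–0.075/yr; the top printed band is extended to the maximum age), with
  a single ×2.3 when obesity and/or diabetes is present — the two conditions
  were assumed to carry identical cardiovascular risk, so one common factor
  is applied even when both are present (`cvd_or_mode="multiplicative"`
  compounds them instead).
- **Psychiatric disorder** (absorbing): odds 0.007/yr, ×4.5 while abusing
  drugs.
- **Judiciary interaction**: odds 0.002/yr, ×4.14 while abusing drugs, ×227
  the year after an interaction (recidivism).
- **Employment**: drawn once at 18 from odds 12.7 (×1.88 if graduated) and
  then held fixed, except re-drawn with an additional ×0.029 in the year
  after a judiciary interaction. The graduation OR is retained in the
  re-draw, since it modifies the same underlying employment odds.

### Persistence conventions

The three persistence inputs (obesity 331, drug abuse 47.6, judiciary 227)
were back-calculated by the original analysts from annual retention or
recidivism rates, in a way that makes the *product* base-odds × OR numerically
equal to the intended retention probability (e.g. 0.003 × 331 = 0.993, the
annual probability of remaining obese implied by "odds 0.007 of
non-persistence"). Treating that product as odds and converting with
odds/(1+odds) — the convention used everywhere else in the model — instead
yields a retention probability of about 0.50/yr, which substantially weakens
the adult disease cascade.

Both conventions are implemented:

- `persistence_mode="odds_ratio"` (default): the product is odds, converted
  like every other transition. This is the literal application of the
  printed composition rule.
- `persistence_mode="probability"`: for individuals in the persisting state,
  the product is read as the annual retention probability (clipped at 1);
  incident draws are unaffected.

The default is the literal rule; the package makes no attempt to decide
which the original software actually computed. The README's worked example
shows the consequence of the choice on the headline contrast.

## Mortality

Background mortality comes from an age-indexed life table of annual death
probabilities q(age). The per-year death probability is q(age) multiplied by
excess-hazard factors for active conditions — cardiovascular disease 2.0,
diabetes 1.5, drug abuse 1.5 — capped at 1. These multipliers are not
printed inputs; they are calibration knobs. `calibrate_mortality` scales
their excess parts (m → 1 + s·(m − 1)) by bisection so that the simulated
remaining life expectancy of an 18-year-old entering adulthood obese matches
a validation target (60.1 years by default, appropriate when running against
the 2008 US national life table). On the bundled synthetic table that target
exceeds even the disease-free life expectancy, so the calibration detects an
out-of-bracket target, warns, and leaves the defaults effectively in place.

### Life tables

Real tables load from a CSV with columns `age,qx`, contiguous one-year ages
from 0. The bundled synthetic generator uses a Gompertz hazard,
q(age) = 1 − exp(−a·e^{b·age}), with defaults a = 10⁻⁴, b = 0.085/yr chosen
to give a life expectancy at birth near 79 years — a realistic
monotone-increasing adult mortality schedule. It reproduces the shape of a
period life table but not its infant-mortality hook, cause-of-death
structure, or cohort trends; tests passing on it demonstrate internal
consistency of the simulation and direction of effects, not agreement with
any national population's magnitudes. The terminal age's q is forced to 1,
and anyone alive at the scenario maximum age (105) dies at the end of that
cycle.

Life expectancy is computed by the standard cohort method as the expected
number of completed years, Σₜ Πₖ(1 − q(a+k)), matching the simulation's
whole-year life-year accounting; a half-cycle correction is available but
off by default.

## Outcomes and costing

Annual cost is the sum over active conditions: drug-abuse treatment $1000;
diabetes treatment $9975; obesity treatment $0; psychiatric (drug
complication) $21,483; cardiovascular disease $1575 when diabetic, $732 when
only obese; incarceration $28,893 in an interaction year; unemployment
opportunity cost $33,160. Utility is the minimum across active conditions
(obesity 0.71; diabetes 0.69; drug abuse 0.67; psychiatric 0.60;
cardiovascular 0.35 with diabetes / 0.50 with obesity alone; prison 0.725 in
the interaction year), 1.0 when healthy; unemployment carries no utility
penalty to avoid double counting with its cost. A cardiovascular flag in an
individual who is currently neither diabetic nor obese (possible through
background incidence, or after late-life obesity remission) carries no
modeled complication cost or disutility, since sequela costs attach to their
parent disease state.

Costs and QALYs are discounted to model entry (age 5) at 5%/yr; the
intervention arm is charged the amortized per-student program cost once at
entry, undiscounted — the same convention that makes 72 students over a
5-year capacity lifetime cost $888.89 each ($320,000 total). Program-cost
rows printed per-child/per-school in the input table are stored in the
registry as provenance but the scenario costing uses the capacity/annual
breakdown, which is what the published per-student figure derives from.

## Random numbers and pairing

One stream per decision (each childhood event; each of the eight adult
events in each model year), derived from the master seed; individual *i*
always consumes the *i*-th variate of each stream. Hence (a) an individual's
trajectory is independent of cohort size and batching, and (b) the two arms,
run from the same seed, share every random input — common random numbers —
so a null intervention produces bit-identical arms and paired contrasts have
substantially smaller Monte-Carlo error than independent runs. Transitions
with forced outcomes still consume their variate, keeping streams aligned
across parameter settings.

## Sensitivity and threshold analysis

One-way analysis reruns the CRN-paired comparison with each parameter pinned
at its lower and upper plausible bound (age-banded parameters move all bands
to their bounds together). Parameters with degenerate ranges yield
zero-spread entries with a warning when explicitly requested, and are
omitted from automatic enumeration. Threshold search bisects the
CRN-smoothed net cost to a relative tolerance of 10⁻³ of the bracket, after
verifying a sign change (the error reports both endpoint values). The
program price per student enters the contrast as an exact additive constant
under CRN, so its threshold — and the integer scan over school sizes — reuse
a single gross comparison; this is algebraically identical to re-simulating
at every candidate value. Registry parameters without printed ranges
(program costs; the obesity-persistence OR and the utilities, which default
to ±50% with utility bounds clipped at 1) are varied only if a range exists.

## Parameter registry conventions

Every printed model input has a stable snake_case identifier, a point value,
and a plausible range; the registry validates low ≤ value ≤ high, utilities
in [0,1], and contiguous age-band tiling. One deliberate exception survives
validation as a flagged finding rather than an error: the over-60 obesity
value −0.002 lies below its printed lower bound of 0 and is stored as
printed (its remission interpretation lives in the transition code, not in
the stored number). Overrides are copy-on-write; a scalar override of an
age-banded parameter rescales all bands proportionally.

## Problem sizes and numerical choices

The test suite runs cohorts of 10³–10⁵ individuals and up to 10⁶ draws for
per-transition frequency checks, with Monte-Carlo assertions at three
standard errors; the directional base-case checks use 10⁵ individuals.
Stochastic tests fix their seeds. Death probabilities are capped at 1 after
multiplier application; adjusted odds are validated nonnegative and finite;
probability-mode retention is clipped at 1.

## Known limitations

- The joint-state structure of the original implementation (its "32 Markov
  states") is under-specified; tracking attributes directly is faithful to
  the stated dependencies but need not match it exactly.
- Disease-specific excess mortality is unpublished; the defaults are knobs,
  and the calibration target is only meaningful against a real life table.
- The persistence-convention ambiguity (above) changes the sign of the net
  cost contrast at realistic program prices; conclusions about cost savings
  should be reported under both conventions.
- Graduation→judiciary, health→employment, and childhood service-cost
  channels are deliberately excluded, mirroring the source model's scope.
- All costs are fixed 2015 $US with no inflation or wage growth across the
  lifetime.
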