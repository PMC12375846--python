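# Methods

## Scope and design

`prostasim` is a discrete-event, person-level microsimulation of prostate
cancer natural history coupled to a screening-policy engine, an economics
layer and cost-effectiveness machinery.  Every stochastic quantity is a
pure function of `(master_seed, person_id, purpose, slot)`, realized
through splitmix64-based counter substreams.  This is the load-bearing
design choice: it gives an exact common-random-numbers (CRN) contract —
the same man has an identical natural history under every strategy, his
no-screening counterfactual twin is exact, scenario differences are
attributable to the overrides alone, and adding a strategy never perturbs
another strategy's draws.  Test and participation draws are keyed by
(person, age in quarter-years), so a man screened at the same age by two
strategies receives the same measured PSA and the same acceptance
decision.

## Natural history

**Other-cause death** is sampled from an annual life table (piecewise
constant hazard, ages 35–105, deaths capped at 105).

**Onset.**  Preclinical onset follows a Weibull hazard in age from 35
(shape 3.0, scale 31 years) applied within a susceptible fraction
(default 0.22); the non-susceptible majority never develops disease.  The
susceptible fraction extends the plain Weibull because an
everywhere-increasing population hazard cannot produce the registry
pattern of incidence rising to the early 70s and declining afterwards;
with a saturating onset distribution the onset flow, and hence diagnosed
incidence, peaks and falls.  Defaults were chosen once so the synthetic
epidemiology is German-like: ~12 % lifetime diagnosis without organized
screening, ~22 % metastatic at diagnosis, diagnosed grade split roughly
40/35/25 across Gleason < 7 / = 7 / > 7, prostate-cancer death ~3.9 % of
men, incidence peaking between ages 65 and 79.

**Grade** (Gleason < 7, = 7, > 7) is drawn at onset from a softmax whose
logits are linear in onset age (reference age 60), so older onsets skew
aggressive; grade is fixed thereafter (no grade migration).

**Progression.**  Local extent advances T1→T2→T3 with grade-specific
exponential clocks (e.g. 0.055/0.11/0.20 per year for T1→T2).  A
metastasis clock runs from onset with grade-specific base rates
(0.004/0.018/0.06 per year) scaled by current local extent
(×0.25/1/2), sampled by piecewise-constant-hazard inversion.  The
3 × 2 × 3 = 18 combinations of extent × metastasis × grade are the
model's disease states.

**PSA.**  log PSA is linear in age: population baseline 0.6 ng/mL at 35,
pre-onset slope 0.025/yr, person-level normal intercept (SD 0.45) and
slope (SD 0.004) deviations, switching continuously at onset to a
grade-specific slope (0.09/0.14/0.22 per year).  Measurement noise is
multiplicative log-normal (SD 0.20) and applied only to measured values.

**Clinical presentation** has hazard ξ(stage) · PSA(t) with
ξ = 0.0035/0.01/0.022 per (ng/mL)·yr for T1/T2/T3 and ×8 once metastatic;
because PSA grows exponentially the cumulative hazard has a closed form
per stage interval and is inverted exactly with one exponential draw.

**Survival and stage shift.**  Cause-specific survival after diagnosis is
a mixture cure model S(t) = c + (1 − c)e^(−rt).  Localized disease: cure
0.90/0.65/0.40 by grade, rate ln(2)/15 / 0.0693 / 0.099 per year,
multiplied by 1.0/1.4/2.0 for T1/T2/T3.  The grade-group-1 localized (T1)
curve therefore evaluates to 0.90 + 0.10·2^(−1) = 0.95 at 15 years — the
model's anchor assumption that low-grade cancer still carries long-term
harm.  Metastatic disease: cure 0.07/0.05/0.03, rate 0.139/0.173/0.225.
A screen-detected cancer draws survival from the curve of its stage at
detection, with the clock starting at the counterfactual clinical
diagnosis age, using the same reserved uniform in both arms; since cure
is non-increasing and rate non-decreasing along the stage ordering, the
paired draw under earlier detection is never shorter (stochastic
dominance by construction).  A case with no counterfactual clinical
diagnosis (overdiagnosed) never dies of cancer.

## Screening engine

Policies are declarative (`StrategyDefinition`): ages, PSA risk bands
with per-band rescreen intervals, work-up threshold, MRI triage flag,
biopsy type, participation.  Invitations are issued while the invitation
age ≤ stop age; an interval overshooting the stop age ends the programme.
Participation follows the published defaults: 75 % are ever-attenders
(drawn once per person; never-attenders exit after the first invitation),
rescreen acceptance 95 % per invitation, biopsy acceptance 65 % per
referral.  Rescreen non-attenders are re-invited (PSA arms after 2 years,
DRE annually).  After a negative work-up the next invitation comes at the
high-risk interval (2 years).

Detection is governed by `TestProfile`s: DRE sensitivity rises with local
extent (0.18/0.40/0.60, metastatic 0.80; specificity 0.94); MRI separates
significant from insignificant disease (sensitivity 0.55 for GS < 7, 0.93
/ 0.95 for GS = 7 / > 7; specificity 0.70 in men without cancer) — the
mechanism by which MRI triage cuts benign biopsies and overdiagnosis;
biopsies detect with grade-specific sensitivity (systematic 0.70/0.82/0.90,
combined 0.75/0.92/0.96) and never yield false positives.  These are
literature-informed placeholders, all configurable.

Symptomatic presentations before any screen detection are realized at the
counterfactual clinical diagnosis age with the arm-appropriate work-up:
MRI + combined biopsy in MRI arms and in the no-screening arm,
systematic biopsy otherwise.  The work-up MRI of symptomatic cases is
costed but not counted as a screening MRI event, mirroring the reporting
convention of screening analyses.

Active surveillance monitoring: PSA + DRE quarterly for two years then
biannually; MRI + combined biopsy at 18 and 36 months, then every three
years (the configured midpoint of the guideline's 12–18-month range).

## Treatment and economics

Treatment assignment is a config rule: metastatic → ADT/chemotherapy;
localized GS < 7 diagnosed at ≤ 70 → active surveillance; other localized
at ≤ 75 → radical treatment (one-time cost, ten years of follow-up
visits, a post-treatment utility phase); older → ADT.  Cancer deaths are
preceded by 2 years of ADT/chemo and a 6-month terminal phase.  AS
continues until death or, for men who will die of cancer, until the
palliative pathway begins; its progression follows the untreated natural
course.

Costs are per-event and per-year in 2023 €.  The PSA test (€25.61,
including the reflex PSA added to a positive DRE) and the MRI (€500 base
case, €120 scenario) are fixed published values; the remaining entries
(biopsies €360/€740, radical treatment €13,000, ADT/chemo €8,000/yr,
palliative €15,000/yr, visits) are documented placeholders.  The balance
between diagnostic/overtreatment spending and end-of-life savings was set
once, at generator-design time, so that the synthetic conditions
reproduce the qualitative cost ordering of organized-screening analyses
(annual DRE costliest); absolute cost levels are not calibration targets.

Discounting is 3 %/yr from age 45; events before 45 discount at factor 1.
Ongoing costs integrate the discount factor in closed form.  QALYs use
the multiplicative model — background utility by age (0.92 at 45 falling
to 0.74 at 85) times active state utilities — accumulated as per-state
disutility rectangles of configured duration (the first-order expansion
of the product; overlapping states are rare and the approximation error
is far below Monte-Carlo noise).  The base integral uses annual midpoint
discounting, which keeps QALY ≤ LY exactly.  Two utility sets ship
(PORPUS-U-style, EQ-5D-style, the latter uniformly lower); swapping them
changes QALYs only, bit-for-bit.

The vectorized cohort engine and the per-person event-log accumulators
implement the same rules; a test asserts their agreement to ~1e-9 on
sampled persons, including stage-shifted screen-detected cases.

## Calibration

Free parameters: onset scale, susceptible fraction, and the two
grade-mixture intercepts (the Weibull shape and all progression,
diagnosis and survival parameters stay fixed — they are weakly identified
by incidence and grade data alone).  The objective simulates a cohort
under background opportunistic DRE (assumed uptake: 50 % ever-attenders,
40 % of annual offers, 65 % biopsy acceptance — the registry-period
statutory offer; the true uptake is not published and ships as a config
assumption) and sums a Poisson deviance over age-group incidence and a
multinomial deviance over grade proportions.  Optimization is Nelder–Mead
with common random numbers (the objective is deterministic given the
seed) and three restarts from the incumbent: on this objective a single
simplex collapses prematurely; restarts recover the optimum reliably.
At 100,000 simulated men per evaluation the fit recovers the true onset
scale and susceptible fraction to ~1–3 % and grade probabilities to
< 0.01 absolute in roughly three minutes on one CPU.  Mortality
validation compares simulated age-specific cancer mortality with exact
(Garwood) Poisson intervals against the targets; no fitting.

## Sensitivity analyses

Deterministic scenarios are dot-path overrides on the nested base
configuration, run on the same cohort and substreams; shipped presets
cover reduced MRI prices (€120 and −50 %), dropping rescreens for
PSA < 1.5 with a 4 or 3 ng/mL threshold, 0 %/5 % discounting, the EQ-5D
swap, DRE stopping at 70, raised ADT/chemo costs, and participation
variants (50/80/50 and 100/100/100 %).  The probabilistic analysis draws
test characteristics, costs and utilities (beta for probabilities and
utilities, gamma for costs, with assumed coefficients of variation since
no variances are published) independently per iteration, re-runs
screening and economics for all strategies on a shared natural-history
cohort, and feeds the per-iteration (cost, QALY) pairs to the CEAC
(ties split equally; probabilities sum to one by construction).  The
reference configuration for a full analysis is 1000 iterations of one
million men; the shipped defaults (200 × 100,000, and smaller in the
analysis scripts) are desk-scale choices.

## Problem sizes and runtime

Natural-history simulation runs at ~0.4 s per 100,000 men; a strategy
(screening + economics) adds ~0.5–2 s.  The analysis scripts use 50,000
men for the base-case comparison and 20,000 for the scenario sweep; the
acceptance suite runs the ten-strategy qualitative checks at 100,000 men
and the parameter-recovery loop at 100,000 men per objective evaluation.
Per-100,000 outcome tables are scaled from these cohorts; Monte-Carlo
noise on rare outcomes (e.g. overdiagnosed counts in short arms) is a few
percent at these sizes.

## What the synthetic data do and do not show

The generator emulates registry-style inputs — a Gompertz–Makeham life
table (life expectancy ≈ 36 years at 45), age-group incidence under
background DRE with Poisson noise at national-registry person-years,
grade proportions and cancer mortality — from a known ground truth.
Passing tests therefore demonstrate internal validity: the estimators
recover known parameters, the CRN identities hold, the comparison and
frontier arithmetic reproduces published-table calculations exactly, and
the strategy ordering matches the published qualitative pattern.  They do
not demonstrate that the shipped parameter values reproduce German
absolute outcomes: real registry data, period and cohort effects,
registry completeness artefacts, opportunistic PSA testing and the
original model's fitted parameters are all outside the synthetic frame.

## Numerical choices and edge cases

Hazard inversions are closed-form (no time stepping); ties between death,
clinical presentation and screening events resolve by event priority
death > clinical diagnosis > screen.  Zero-rate clocks mean "never", not
"immediately".  Uniform draws are clipped away from {0, 1} before logs
and normal quantiles.  Survival draws with u below the cure fraction
return +∞ (cured).  Degenerate inputs (empty cohorts, zero person-years,
unresolvable override paths, missing test profiles, negative rates)
raise typed errors before any simulation.

## Known limitations

No grade progression after onset; clinical-diagnosis hazard depends on
PSA and stage but not on age directly; one biopsy per symptomatic
diagnosis (no repeat-biopsy cascades); AS progression follows the
untreated natural course rather than a treated one; independent marginals
in the probabilistic analysis; no opportunistic PSA testing in the
background; societal costs and value-of-information are out of scope.
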