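# Methods

## Model structure

The package implements a three-state partitioned survival model. Given an
overall-survival curve OS(t) and a progression-free-survival curve PFS(t)
for a strategy, state occupancy at every time point is

- progression-free: PF(t) = PFS(t)
- post-progression: PP(t) = OS(t) − PFS(t)
- dead: D(t) = 1 − OS(t)

No transition probabilities are estimated; the curves *are* the model. The
approach assumes PFS(t) ≤ OS(t) everywhere (see "Curve crossing" below) and
that the published curves adequately describe the cohort over the horizon.
Cohort size is irrelevant: all quantities are expectations over state
proportions.

Time is measured in years throughout; dosing intervals given in weeks are
converted at 365.25 days/year (one q3w cycle = 21/365.25 years). The
default horizon is 5 years and the default discount rate is 0 (a 3% rate is
one flag away; every life-year and cost integral accepts a rate).

## Effectiveness

The primary effectiveness measure is quality-adjusted progression-free
life-years saved:

QA-PFLYS = ∫₀^H u_eff(t) · PF(t) · e^(−rt) dt

with u_eff(t) equal to the on-treatment utility (default 0.84), reduced
during the toxicity window [0, d) by the probability-weighted grade ≥3
toxicity multiplier 1 − p·(1 − u_tox). QALYs add the post-progression term
∫ u_pp · PP(t) · e^(−rt) dt with u_pp = 0.50. QA-PFLYS is the primary
measure because trial crossover at progression confounds OS-based
comparisons; QALYs are reported alongside.

Two on-treatment utility values circulate for this population (0.80 and
0.84); the bundled scenarios use 0.84, and the value is a single config
field (`utilities.on_treatment`) for anyone preferring the alternative.

## Costs and schedules

Each regimen is an induction phase (six q3w cycles of immunotherapy +
carboplatin/paclitaxel, or chemotherapy alone at $1,126/cycle) and an
optional maintenance phase. 2024 USD per-cycle costs: induction triplet
14,462 (dostarlimab) / 13,464 (pembrolizumab) / 10,146 (durvalumab);
maintenance 26,672 q6w / 24,676 q6w / 12,081 q4w respectively. Grade ≥3
toxicity probabilities 0.71 / 0.63 / 0.54 (0.53 for chemotherapy alone),
costed once at model start as probability × cost (9,784 for the
immunotherapy triplets, 9,163 for chemotherapy), with utility multiplier
0.70 over a default window of 18 weeks (the induction length).

Dose delivery follows the modelling rule that patients receive three cycles
before progression status can stop treatment: the first `guaranteed_doses`
(default 3) administrations are always delivered; every later dose at time
t contributes with probability PFS(t), evaluated exactly at the dose time
(no half-interval correction). Stopping rules are encoded as a per-phase
dose cap plus a total-treatment-time cap measured from treatment start:
pembrolizumab 2 years total; dostarlimab up to 42 maintenance cycles and a
3-year cap (a 2-year variant ships for comparison); durvalumab until
progression, with 2- and 3-year capped variants. The time cap is applied
uniformly from treatment start for all drugs — the trial protocols phrase
their caps slightly differently (total-time vs additional-cycles), and one
consistent encoding keeps the 2-year/3-year variants directly comparable.

The per-administration price of the immunotherapy component is an explicit
parameter (`immuno_price`, the triplet cost minus the $1,126 chemotherapy
backbone), with a per-phase multiplier reflecting the maintenance dose size
(2× for the q6w double doses of dostarlimab and pembrolizumab, 1500/1120
for durvalumab). Total drug cost is therefore exactly linear in that price,
which the threshold analysis relies on.

A flat post-progression care cost rate (USD/year in the PP state) is
supported and defaults to $0/year: the incremental comparisons the package
is built around are insensitive to any value shared across strategies, and
no defensible published rate was available to bundle.

## Numerical choices

- **Step curves integrate exactly.** Restricted areas of digitized
  (Kaplan–Meier) step curves — including the discounted case — are computed
  as closed-form segment sums, not quadrature. When both curves of a
  strategy are steps, the evaluation grid is the union of a weekly grid and
  the curves' jump times, and occupancy integrals use exact discounted
  rectangle sums. This makes the deterministic engine agree with
  patient-level simulation up to Monte-Carlo error only.
- **Smooth curves use high-order quadrature.** Parametric curves integrate
  by adaptive quadrature (restricted areas) or Simpson's rule on the weekly
  grid (occupancy integrals); both reproduce exponential closed forms to
  better than 1e−6 relative.
- **Extrapolation** past the last digitized time point holds the last value
  by default; an exponential tail fitted to the final quarter of follow-up
  is available per curve (`extrapolation="exp_tail"`).
- **Curve crossing.** Digitized PFS may exceed OS by pixel error; excesses
  up to 0.005 are clamped down to OS with a warning, larger ones raise an
  error naming the first offending time.
- **Dominance.** A strategy that is cheaper and more effective than the
  comparator is flagged dominant (and dominated in the mirror case) instead
  of printing a negative ICER; a zero effect difference reports the ICER as
  undefined.
- **Break-even price.** p* = p₀ − (ΔC(p₀) − WTP·ΔE)/N with N the expected
  discounted number of priced administrations; the test suite verifies the
  closed form against Brent root-finding on the full engine to $0.01 and
  that the engine ICER at p* equals the threshold to 1e−6 relative.
- **PSA tie-breaking.** With fixed parameters two strategies can tie on net
  monetary benefit; ties resolve to the lowest-cost strategy, keeping
  results deterministic. One seeded generator drives each PSA run; the same
  seed yields bit-identical output.

## Sensitivity-analysis defaults

One-way ranges default to ±20% of base for costs and durations and ±10%
(truncated to [0, 1]) for probabilities and utilities — a ±20% band on a
0.84 utility would exceed the feasible range, and ±10% mirrors the PSA's
standard-error convention for bounded quantities. PSA distributions: gamma
for costs (mean = base, SE = 20% of base), beta by method of moments for
probabilities and utilities (SE = 10% of base), lognormal (mean 1,
SE = 0.1) for a per-strategy proportional-hazards perturbation applied to
both curves, which propagates treatment-effect uncertainty without letting
PFS cross OS. A `normal` family is also available for parameters with
genuinely symmetric uncertainty. Draws are independent across parameters
and iterations; no correlation structure is imposed. The CEAC is evaluated
on a $0–300,000 grid in $10,000 steps, covering both the $100,000 base
threshold and the higher thresholds discussed for oncology drugs.

## Synthetic trial generator

The generator stands in for digitized trial Kaplan–Meier curves. Per
patient, progression time is Weibull (shape 1 = exponential by default)
with scale set from the control-arm median PFS; death time is progression
plus an exponential post-progression survival draw whose median is the
control OS–PFS median gap (floored at one month). Building death on top of
progression guarantees OS ≥ PFS for every patient, so the partition never
encounters curve crossing on synthetic data. The treated arm applies the
trial hazard ratio by proportional-hazards rescaling of the progression
distribution; post-progression survival is assumed unaffected by prior
treatment (hr_os = 1 in the presets), so OS gains flow entirely from
delayed progression. Censoring is administrative only, at end of follow-up.

The bundled scenarios use the published PFS hazard ratios — dMMR:
dostarlimab 0.29, pembrolizumab 0.30, durvalumab 0.42; pMMR: pembrolizumab
0.54, dostarlimab 0.76 — against control medians typical of the
chemotherapy arms (dMMR 7.7 months PFS, pMMR 8.7 months; OS median 2.3
years). All treated arms share a single simulated control arm, since the
model compares every regimen against one chemotherapy strategy. The presets
simulate 5,000 patients per arm: the curves play the role of digitized
population-level estimates that the downstream analysis treats as fixed
inputs, so they are generated with little sampling noise; trial-scale noise
(a few hundred patients per arm) is one `TrialSimSpec` field away for
anyone studying its effect. Preset seeds are fixed (dmmr 2024, pmmr 2025)
so the bundled scenarios are reproducible documents rather than fresh
draws.

What the generator does **not** emulate: the actual published curve shapes
(non-proportional hazards, plateaus from durable responders), dropout or
informative censoring, cure fractions, and correlation between progression
and post-progression survival. Tests passing on synthetic data therefore
validate the *engine arithmetic* — partitioning, accumulation, incremental
analysis, threshold pricing, PSA machinery — not the clinical conclusions
one would draw from real digitized curves, whose ICERs differ from the
synthetic ones at the tens-of-percent level.

## Known limitations

- QA-PFLYS credits no utility to post-progression survival; strategies that
  mostly extend post-progression life are better judged on the QALY output.
- The 33%/67% dMMR/pMMR prevalence split is carried as scenario metadata
  only; no prevalence-weighted pooled ICER is computed, matching the
  subgroup-stratified reporting convention.
- Per-patient dose individualization (body-surface-area pricing, vial
  sharing, wastage), second-line treatment sequencing beyond the flat
  post-progression cost rate, and lifetime-horizon extrapolation are out of
  scope.
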