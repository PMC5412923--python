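# Methods

## Model

Each active participant contributes one binary response, y = 1 if the dose
was *ineffective* for them (drug concentration not maintained sufficiently
above the IC50), modelled as y ~ Bernoulli(p(d)) with the one-parameter
logistic curve

    logit(p) = α − β d,    α = 5 fixed,    β > 0,

on standardised doses d = mg/10 (a backward-fitting standardisation: at
β = 1 a dose with anticipated inefficacy P maps to d = 5 − logit(P), and
the anticipated curves put the eight 10–80 mg doses close to d = 1…8).
The fixed intercept encodes two structural assumptions: the probability of
inefficacy at dose zero is essentially 1 (expit(5) ≈ 0.993 — an untreated
participant fails), and the curve decreases monotonically in dose for any
β > 0. A one-parameter family is deliberate for an 18–20 participant
trial: it estimates the right-hand tail of the curve near the target dose
rather than the whole curve. The module exposes the curve, the
standardisation, the Bernoulli log-likelihood and the posterior; other
one-parameter families could be slotted in at the `ModelSpec` level but
are not implemented.

## Inference: deterministic quadrature

The posterior over β is one-dimensional, so it is computed by midpoint
quadrature: the support (0, β_max] is split into `n_beta` equal cells
(default 4001, β_max = 10), the unnormalised log-posterior is accumulated
in log space (log-prior + count-weighted `log_expit` terms, max-subtracted
before exponentiation), and the normalised cell masses are the posterior.
At β = 10 even the 10 mg dose has inefficacy probability below 0.01, so
the truncation carries no practical mass; β_max is configurable.

Quantiles (median, credible limits) interpolate linearly *within* a cell,
treating the posterior as a piecewise-constant density. This makes the
median and interval endpoints converge smoothly as the grid is refined
(observed changes < 1e-4 when doubling the resolution) instead of jumping
by one cell width. Per-dose credible intervals are the image of the
central β interval under the monotone decreasing curve.

Two per-dose point estimates are retained: the plug-in curve at the
posterior median of β (the default convention, used by all decision
rules and matching how the estimated curve is usually drawn), and the
posterior mean of each p(d). The active convention is a `ModelSpec`
switch. A deterministic engine was chosen over MCMC so that the dose
decisions in a realisation are an exact function of the data; an
independent random-walk Metropolis sampler is kept in the test suite as a
cross-check (agreement within 0.01 on per-dose posterior means).

## Prior

The slope prior is configurable; the default is Uniform(0, 10), chosen to
be vague on the probability scale: its prior-predictive 90% bands span
nearly the whole [0, 1] range at most doses, which is the stated behaviour
of the original trial's prior (whose exact form is not public). An
Exponential(mean 2) family (and Gamma) is provided for sensitivity
analysis; under Scenario 1 the adaptive design's operating
characteristics move by at most a few hundredths across these diffuse
choices, and the rule-based selection probability of the target dose is
essentially unchanged (~0.57 under every prior/rule/convention
combination tried).

## Designs

* **Fixed 5+5+5+5**: 5 active participants at each of 10/20/40/80 mg,
  rule-based selection only. Placebo participants are ignored throughout.
* **Adaptive**: period 1 = 2 active participants at each of 10/20/40/80 mg
  in escalating order; period 2 = 5 cohorts of 2, posterior refit before
  each, next dose = grid dose with estimated inefficacy closest to the
  TIL (ties to the higher dose; dose skipping permitted — the model may
  jump to a never-administered dose). An alternative Ji-style rule —
  maximise the posterior mass of p(d) inside [TIL − δ, TIL + δ],
  δ = 0.025 — is available behind `decision_rule="interval"`. Period 3
  (optional, default off) doses 2 confirmation participants at the
  model-selected dose and is skipped when that selection is "none";
  period-3 responses never feed back into selection. The default is off
  because the published per-dose allocation means for the adaptive
  designs sum to 18 participants.
* **Final selection** on period 1–2 data: rule-based (lowest administered
  dose with a failure-free chain at and above it) and model-based (lowest
  grid dose with estimate strictly below the TIL). The asymmetry between
  "closest to TIL" allocation and "below TIL" selection is intentional:
  under-dosing the confirmatory stage is considered worse than
  over-dosing it, which is also why ties break upward.

## Scenario bank

Scenario 1 is fully specified (true inefficacy 0.95/0.75/0.40/0.05/0.04/
0.03/0.02/0.01 at 10…80 mg; target 40 mg). The target dose of any
scenario is the dose with the *highest* inefficacy probability ≤ 5%
(the lowest qualifying dose on a monotone curve; the literal
highest-probability form also resolves non-monotone curves sensibly).
Scenarios 2–7 of the bank are **emulated**: their exact probability
vectors are not public, so parametric generators reproduce each one's
documented constraints instead — logistic-like curves with targets at
60 mg, 80 mg (upper boundary), none (no effective dose) and 10 mg (all
doses effective), a shallow curve (steepness 0.5 vs the default 1.75,
same 60 mg target), and a reverse-J curve that copies Scenario 1 up to
40 mg then rises by 0.15 per step (auto-induction). The logistic
generator places the 5% crossing midway between the target and the dose
below it, which guarantees the target by construction for any positive
steepness; the default steepness 1.75 matches the average logit slope of
Scenario 1's printed head. Emulated scenarios are suitable for studying
design behaviour, not for reproducing the original per-scenario tables
cell by cell.

## Simulation engine

`simulate_design` draws independent realisations from one master
`SeedSequence` with per-realisation child streams, so results are
reproducible and order-independent; identical seed and configuration give
byte-identical output. Operating characteristics are stored at full
precision; tables round to 2 decimals. For scenarios without a target
dose the below-target count is reported as not applicable. The fixed
design additionally has an exact enumeration oracle: rule-based selection
depends only on which of the four administered doses are failure-free, so
16 joint patterns with probabilities (1 − p_d)^5 enumerate the selection
distribution exactly; the stochastic engine agrees with it within Monte-
Carlo error at 100,000 realisations in the test suite.

Problem sizes: design comparisons default to 1000 realisations per cell
(a 5% TIL Scenario-1 cell takes a few seconds); the acceptance script
uses 1000 realisations for the fixed-design quantities and 10,000 for the
adaptive selection probability, where the extra precision (3 SE ≈ 0.015)
is warranted by the wider comparison tolerance on that quantity.

## Summary measures

SM1 = P(select target or higher), SM2 = P(target or one step higher),
SM3 = P(target), SM4 = P(target or one step either side), computed from
the selection distribution of a chosen criterion; with no target dose all
four equal P(select no dose). The weighted summary measure is

    WSM = p(d_t) + Σ_{i=t+1}^{min(8, t+4)} p(d_i)(1 − (i − t)/5) − 2 p(none),

doses indexed 1–8 as mg/10. The upper limit is implemented as
min(8, t+4): the published formula prints max(8, t+4), but its own worked
example for a 60 mg target (terms up to dose 8 with weights 0.8 and 0.6)
is consistent only with min, so the printed max is treated as a typo.
SM4 is taken literally: the dose below target counts as "good" even
though its true inefficacy exceeds the tolerable level.

## What the simulations do and do not show

The generator draws independent Bernoulli responses from the scenario
curve — no placebo arm, no safety stopping, no PK-endpoint ambiguity
(day-4 vs day-7), no dropout, and no delay between cohorts. Passing
operating-characteristic checks therefore validates the decision logic
and its statistics under idealised response generation, not trial conduct.
One known consequence of the deterministic inference engine: allocation
trajectories are less dispersed than under MCMC-driven decisions, because
the closest-to-TIL rule acts as an attractor once the posterior settles
(e.g. a failure-free 30 mg cohort keeps drawing further 30 mg cohorts
until a failure occurs). This concentrates both allocation and rule-based
selection slightly more on the target dose than a sampler-driven
implementation of the same design, while the model-based selection
distribution is essentially unaffected.

## Degenerate inputs and numerical guards

Probabilities of exactly 0 or 1 are rejected where their logit is needed;
negative standardised doses are rejected; empty histories return the
prior; an all-underflow posterior raises `PosteriorUnderflowError` rather
than renormalising garbage; rule-based selection requires a non-empty
history; scenario probabilities are validated into [0, 1]. Exact ties in
the closest-to-TIL rule (including floating-point ties at 1e-12) break
toward the higher dose.
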