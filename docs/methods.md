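# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the tests do and do not demonstrate.

## Scope and design

The package implements a closed-loop management strategy evaluation for a
three-species groundfish complex under climate forcing. It deliberately
replaces two heavyweight upstream components with transparent stand-ins:

- the ocean/plankton model chain is replaced by a **synthetic forcing
  generator** (linear warming trends plus Gaussian interannual noise, with
  zooplankton and cold-pool indices derived from temperature), because the
  downstream models consume only annual scalar indices;
- the bioenergetics predation sub-model of a full multispecies assessment is
  replaced by a **configurable predation term**
  `M2_prey,a = Σ_pred coef · vuln_a · B_pred · exp(slope · anomaly)` —
  linear in predator biomass, exponential in temperature anomaly — chosen
  for testability rather than mechanistic fidelity.

Everything else (bias correction, recruitment, age-structured dynamics,
reference points, control rule, catch functions, cap, risk, tipping
detection) is implemented in full.

## Forcing

Delta-method bias correction under unequal variances, applied independently
per index with sample SDs (n−1 denominator). Over the reference years
(default 2006–2017) the corrected series reproduces the hindcast reference
mean and SD exactly; the operation is idempotent. The cold-pool fraction is
corrected on the raw scale and clipped to [0, 1] afterwards, with clips
logged — the bounded support is not respected by the linear correction and a
transformed-scale variant was judged not worth the added opacity. A
`freeze_after` flag on any scenario holds conditions at a given year's trend
level (generalizing the practice of extending a truncated projection by
holding late-century conditions constant). The persistence counterfactual
carries the reference-period hindcast mean in every projection year.

Default scenario roster: six trajectories in two tiers (moderate ≈
0.016–0.027 °C yr⁻¹, high ≈ 0.030–0.050 °C yr⁻¹ with per-trajectory offsets),
bracketing roughly 1–2.5 °C and 2–4.5 °C of warming over the ~80-year
projection. Interannual noise SD 0.45 °C; zooplankton–temperature slope
−1.6 index units per °C; cold-pool slope −0.12 per °C.

## Recruitment

The recruits-per-spawner model is Ricker-form on the log scale (linear in
−B and the covariates), so Gaussian maximum likelihood is ordinary least
squares; the residual SD uses the degrees-of-freedom-corrected estimator.
The four default covariates are spring and fall large-zooplankton indices,
bottom temperature and cold-pool extent; they are mutually correlated by
construction (all derive from temperature), so individual covariate
coefficients are weakly identified at hindcast sample sizes while the
joint climate signal is well identified — fits report the full coefficient
covariance for exactly this reason.

Projection ensembles draw parameter replicates jointly from
N(estimate, covariance). For the density-dependence coefficient β₀ the
ensemble path uses a moment-matched lognormal through a Gaussian copula:
a Gaussian draw can make β₀ negative, which removes the model's
self-limitation and lets trajectories diverge; the lognormal preserves the
first two moments and the correlation structure while enforcing the sign the
model needs. Process error is drawn fresh each year, i.i.d. N(0, σ²) on the
log scale. Recruits enter at age 1 with a one-year lag from spawning
biomass; spawning is start-of-year. These conventions are this package's,
documented rather than asserted as anyone else's.

## Operating model

Numbers-at-age in thousands of fish, weights in kg, so N·W products are
metric tons. Annual update: survivors shift one age under last year's total
mortality, the oldest age accumulates as a plus group, and recruitment
enters age 1. Weight-at-age responds multiplicatively to the temperature
anomaly, g(x) = 1 + sens·x, clamped below at 5% of baseline with a logged
warning. Fishing is continuous F inside the Baranov equation, never discrete
removal. Inverting catch to an effective F uses bracketed root finding
(Brent, bracket [0, 4 yr⁻¹]); targets beyond the attainable catch cap F at
the bracket top with the shortfall logged.

Species configurations are shaped like a gadid pair plus a flatfish
(10–12 ages, logistic maturity/selectivity, juvenile-elevated M1, weights
rising to ~1.5 kg for the pollock-like species and several kg for the
others), with unfished spawning-biomass scales of roughly 9, 2 and
1.2 million tons — magnitudes typical of the eastern Bering Sea complex, at
which the 2 MT cap can bind in good years. True values of all of these live
in stock assessments and are out of scope; the configs are defaults, not
estimates.

## Reference points and control rule

B0 is the mean unfished spawning biomass over 2095–2099 under persistence
(the window is configurable for short-horizon testing). F_target solves, by
nested bisection with deterministic (ε = 0) projections, for window-mean
spawning biomass equal to 40% of B0: the two gadids alternately until both
depletions converge (tolerance 1e-7), with the flatfish at its
historical-mean F (0.05 yr⁻¹ in the fixture); then the flatfish with the
gadid rates frozen. Each species' 40% criterion therefore holds **under its
own solve conditions**: once the flatfish moves from its historical F to its
own F_target, pollock depletion drifts above 40% because higher flatfish F
releases predation on juvenile pollock. That drift is an emergent
multispecies interaction, not solver error, and the verification helper
reports depletion under the phase conditions accordingly.

The control rule's ramp between the 20% cutoff and the 40% target is a
straight line from (0.20·B0, 0) to (0.40·B0, F_target); the regional tier-3
analytic form `F_target·(B/B40 − a)/(1 − a)` is available via
`hcr_form="tier3"` (a = 0.05). Reference points are derived only from the
persistence scenario — the solver refuses any other forcing.

## Catch functions and the cap

Stage-wise log-linear regressions (ABC→TAC, TAC→catch) estimated
equation-wise by least squares; the three ensemble members share the point
estimates and differ only in the residual grouping (independent, two linked
groups, three linked groups) under which cross-equation residual
correlations are reported. With three equations and ~26 annual observations,
feasible-GLS refinements move point estimates negligibly, and only the mean
relationship is used in simulation, so equation-wise OLS is the estimator.
Ensemble predictions are the unweighted member mean (weights configurable),
exclude the lognormal retransformation term σ²/2 by default
(`retransform_bias=True` adds it), and are clipped to the hard management
constraints TAC ≤ ABC and catch ≤ TAC, with clips logged. Degenerate
regressors (constant columns, including a species' own log-quota if it has
no contrast) are dropped with a warning. The cap rule scales all modeled
TACs by one factor so that modeled + exogenous totals exactly equal the cap
when it binds; it is idempotent and proportion-preserving. The exogenous
block defaults to 0 (cap applied dynamically to the three focal species
only); a fixed block (450,000 t in the analysis scripts) emulates the rest
of a managed complex, the regime in which a system-wide cap historically
binds.

Leave-one-out cross-validation refits both stages per held-out year and
accumulates sums of differences, percent differences, squared differences
and squared percent differences, alongside the same metrics for the naive
catch = ABC rule.

## Closed loop and ensembles

Per year: (1) advance the population and compute ABC from the control rule
against climate-naive B0, using start-of-year biomass; (2) ABC→TAC (identity
without the cap; regressions plus cap with it); (3) TAC→catch, catch→F by
inversion, remove, continue. Replicates pair a single parameter draw and a
single process-error stream across every scenario and variant (common random
numbers), so scenario-minus-persistence contrasts isolate the climate
signal. Default replicate counts are 100 for the unfished and uncapped
variants and 30 for the capped variant; the analysis scripts run 10 per
variant over three scenarios and the full 2018–2100 horizon, and the test
suite uses 2–5 replicates over 15–30 years. Those sizes keep every stage
exercised while the whole pipeline (fixture → fits → reference points →
ensemble → risk → tipping) completes in well under five minutes.

## Risk metrics

ΔC is computed per replicate against the paired persistence run; baseline
zeros are masked with a log entry. Risk probabilities use the **period-mean**
ΔC by default over four near-equal windows spanning the projection
(an "any-year-within-period" variant is a flag), with strict inequalities at
the 10/50/80% thresholds. Threshold nesting P(collapse) ≤ P(severe) ≤
P(decline) holds by construction and is property-tested. Warm stanzas are
maximal runs of ≥5 consecutive years strictly above 2.1 °C.

## Tipping-point analysis

The smoother is a penalized cubic B-spline of basis dimension k (default 4;
interior knots at data quantiles for k > 4) with an exact
integrated-squared-curvature penalty — its null space is exactly the linear
functions, so straight-line data are reproduced to machine precision at any
penalty weight — and the weight chosen by GCV on a log grid. With k = 4 the
basis family is immaterial; the contract is stated in recovery tests, and
one test cross-checks the smooth against an independent thin-plate GAM fit
in R's mgcv.

Derivatives are finite differences (second-order, including edges) on a
200-point grid. Bands come from a residual bootstrap (default 1000 refits at
the fixed penalty weight; failed refits are dropped and logged, >10%
failures abort), pointwise 2.5/97.5 percentiles — read as a 95% interval;
the s″ bounds are loess-smoothed (span 10%) before use. Candidate tipping
points are sign changes of s″; a candidate qualifies if the smoothed s″
interval excludes zero somewhere within a flanking window (10% of the
range each side), scores by the interval's largest distance from zero
there, and ties break toward the larger peak |s″|. The stricter option of
also requiring the s′ interval to exclude zero is not imposed; s′-significant
regions are reported separately. Absence of a qualifying point is a valid
result. The estimator is location-equivariant (knots follow the data), which
is tested.

## Synthetic study conditions

The fixture's effect signs mirror the mechanism the analysis probes: warming
and cold-pool loss depress recruitment, large zooplankton supports it, and
zooplankton declines as the shelf warms — so warm scenarios compound the
stress. Magnitudes are chosen once for plausibility (log-scale temperature
effects of −0.28/−0.22/−0.10 for pollock/cod/flatfish; recruitment σ of
0.55/0.45/0.35). Spawner–recruit observations use a seeded lognormal
random-walk biomass path (SD 0.45 per step) — enough contrast to identify
density dependence — with recruitment generated exactly from the model. The
quota history (1992–2017) comes from the true log-linear relationships with
cross-species-correlated lognormal noise (residual correlation 0.5) and
indicator columns switching on in 1999 and 2008.

What the fixture does **not** emulate: autocorrelated climate noise and
regime shifts, observation/assessment error (the loop conflates operating
and estimation models), spatially structured surveys, age-composition data,
and the archived distributions of any real projection ensemble. Passing
tests therefore demonstrate internal correctness and calibration of the
machinery under known truth, not skill on real Bering Sea data.

## Known limitations

- The predation term is phenomenological; ration, diet composition and
  bioenergetics are out of scope.
- Reference points are climate-naive by design (as in current practice);
  climate-informed B0 variants are not implemented.
- The three-member catch-function ensemble collapses to a single mean
  prediction because members share coefficients; it matters only if the
  optional FGLS pass or member weights are used.
- The tipping detector reports at most one point per pooled panel; truly
  multi-threshold responses are summarized by their strongest inflection.
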