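# Methods

This note documents the models implemented in `phenomatch`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## The analysis in one paragraph

A population of precocial shorebird chicks depends on a seasonal pulse of
terrestrial invertebrates. The pipeline converts raw invertebrate length
records into daily measures of resource *quantity* (summed inferred dry
mass, mg·transect⁻¹·day⁻¹) and *quality* (median per-capita dry mass, mg),
fits logistic growth curves to chick mass captures, estimates daily chick
survival with a Bayesian known-fate model whose covariates vary in time,
and finally asks which population-level representation of phenological
(mis)match — overlap of an age-structured "whole demand" curve, overlap of
a single-timepoint "peak demand" curve, total resource availability, or
peak-date synchrony — best explains variation in annual fledging rates.

## Resource series

- Dry mass from length: `m = a·Lᵇ` per taxonomic order. The shipped table is
  a generic arthropod power law (a = 0.0305, b = 2.62) with per-order
  overrides; these are placeholders in the literature's usual range and are
  intended to be replaced with study-specific coefficients via
  `AllometryTable.from_csv`.
- Potential prey: adults with 1.5 mm ≤ L ≤ 9 mm (closed interval; the gape
  limit of a small shorebird chick), excluding Collembola. Larvae are
  dropped.
- Days on which only a subset of transects reported are averaged over the
  reporting transects rather than imputing zeros, because a missing transect
  is indistinguishable from an unsampled one in the record schema;
  `n_transects` and `n_records` expose coverage. Missing days are left
  missing — trailing means simply skip them, and no interpolation is done.
- Annual peaks: OLS quadratic in day-of-year (internally centered for
  conditioning); the peak is the vertex −β₁/(2β₂), defined only when
  β₂ < 0. Seasons sampled for < 30 days are excluded from peak estimation.
- Trends across years: linear mixed models (REML) of the daily response on
  year with crossed random intercepts for trap type and sample date,
  fitted via variance components on a single grouping (statsmodels MixedLM).
  Predictor and response are standardized internally by twice their sample
  SD (half-SD coefficient scale) and the slope is back-transformed to
  original units per year. CIs are standard Wald intervals; R² values are
  the Nakagawa marginal/conditional variance partitions. Singular fits fall
  back to OLS with a logged warning.

## Growth and body condition

Mass at age a follows `A0 / (1 + exp(−K(a − Ti)))` with A0 fixed at 249 g
(mean adult mass, sexes pooled). Four candidate structures cross constant
vs year-specific K and Ti; every structure carries an individual (chick)
random intercept on K, absorbing unmeasured sex differences. Estimation
maximizes a Laplace-approximate marginal likelihood: the inner step is a
vectorised 1-D Gauss–Newton solve for each chick's K deviation, the outer
step Nelder–Mead with multi-start (jittered restarts, 4 by default,
configurable up to 100). Conditional AIC uses the conditional log-likelihood
at the shrunken deviations plus an effective-df penalty
`p_fixed + Σᵢ Jᵢ/(Jᵢ + σ²ᵦ⁻¹σ²) + 1`, where Jᵢ is each chick's Gauss–Newton
information — the trace of the working mixed-model hat matrix. As the
random-effect variance goes to zero this collapses exactly onto ordinary
AIC (tested to 1e-6).

BCI = observed mass gain over a recapture interval divided by the gain
predicted by the *population* (year-level) top curve over the same ages, so
BCI = 1 means on-curve growth. The BCI model is a Gaussian additive model:
subsets of {daily biomass, daily median body mass, hatch date} as linear
terms plus a penalized cubic B-spline in chick age (8 basis functions by
default, reduced automatically for small n; smoothing parameter by GCV via
statsmodels GLMGam). The resource covariates are trailing means over
{1, 3, 7} days anchored on the recapture day — the day-of-recapture value
*is* the 1-day trailing mean, so the timescale candidate set has three
distinct members — selected by small-sample-corrected AIC at fixed spline
settings. Covariate pairs with |Pearson r| ≥ 0.7 are pruned (later-listed
member dropped). When no subset model reaches weight 0.90, coefficients are
conditionally model-averaged over the ΔcAIC < 4 set with Akaike weights.

## Known-fate survival

Daily survival is logit-linear in standardized covariates — 3-day trailing
biomass and median body mass (matched to the interval end, the relocation
cadence), hatch date, age (interval midpoint), and an age × body-mass
interaction — with random intercepts for brood, year, and plot. Intervals
are cut at relocations; a confirmed carcass or three consecutive not-found
days closes the final interval as a death; chicks alive at 21 days (the
radio lifespan) are right-censored as fledged. A survived or censored
interval contributes Σ log s_d; a death interval contributes
log(1 − Π s_d) over its days, with no death-day imputation for longer gaps.

Priors: coefficients Normal(0, 10) on the half-SD standardized logit scale
(configurable; the indicator-selection tests use a weakly-informative
Normal(0, 1) slab because inclusion odds scale with the slab width);
intercept-SD hyperpriors Uniform(0, 25). Group means are fixed at zero —
with a global intercept the family means are not identified — and each
family is additionally swept to sum to zero after every update, moving its
mean into the intercept. This post-sweeping keeps the intercept identified
even for two-level families (plot) and leaves the likelihood untouched.

The sampler is adaptive Metropolis-within-Gibbs, all linear algebra
vectorised over chick-days: a joint adaptive random-walk proposal for the
coefficient block (Haario-style empirical covariance, frozen after
warm-up), simultaneous independent single-site proposals for each random
intercept family (valid because the likelihood factorises over groups),
log-scale walks for the intercept SDs, and — when selection is on —
Kuo–Mallick indicator flips with exact prior refreshes of excluded
coefficients and forced heredity (an interaction drags its main effects
in). Defaults mirror common field practice: 3 chains × 5000 iterations,
600 adaptation + 1000 burn-in, keep every 3rd draw. This sampler needs more
iterations per effective sample than a specialised Gibbs engine, so the
pipeline exposes the chain settings and the shipped acceptance run uses
3 × 20000. Convergence is judged by split-R̂ < 1.1 and effective sample
sizes (Geyer initial positive sequence); a non-converged fit is returned
with a warning flag rather than discarded.

WAIC is computed from the retained pointwise interval log-likelihoods as
−2(lppd − p_WAIC) with p_WAIC the sum of pointwise posterior variances, and
is cross-checked in the tests against quadrature on a conjugate
Bernoulli–Beta toy. Annual fledging is F = s²¹ per year with the
first-order delta SE 21·s²⁰·SE(s), where s is that year's posterior mean
daily survival averaged over its observed chick-days at the sampled
parameter values (random effects marginalized by construction). The
first-order delta SE is accurate to ~10% for SE(s) ≤ 0.015; at SE(s) = 0.02
the curvature of s²¹ makes it genuinely ~11–15% low, which the tests pin
down against a Monte-Carlo oracle.

## Mismatch metrics and annual models

- Resource curve: daily proportion of the year's total biomass.
- Peak-demand curve: each chick surviving to the growth inflection Ti
  contributes a unit at calendar day hatch + Ti.
- Whole-demand curve: every chick alive on a day contributes predicted
  mass^θ; θ defaults to 0.75 (metabolic allometry), with θ = 1
  (mass-proportional) and θ = 0 (head count) as named alternatives. Chicks
  with interval-censored deaths contribute until the midpoint of the death
  interval.
- Overlap: Σ_d min(consumer_d, resource_d) — symmetric proportional-area
  overlap in annual proportions; a consumer-normalized variant is exposed
  under `demand_coverage`.
- Curve height: area under the unnormalized biomass curve at unit-day
  spacing, i.e. the sum of daily biomass (this, not a literal trapezoid,
  makes the height of the normalized curve exactly 1).
- Peak-date difference: resource vertex minus demand vertex from the same
  quadratic estimator used for annual peaks (positive = resources later).
- Annual models: univariate OLS of fledging rate on each of the four
  metrics, compared by AICc (k = 3) and Akaike weights; ≥ 4 common years
  required.

## Synthetic data

The generator draws every stream from one `SimConfig` with fixed RNG stream
offsets per stage, so partial reruns are stable and everything is
reproducible from (config, seed). It emulates: Poisson daily catches along
two transects with a Gaussian (optionally skewed) seasonal pulse scaled so
the expected per-transect dry-mass flux at the peak equals the configured
height, plus a baseline floor (passive traps rarely catch literally
nothing); per-order lognormal lengths rounded to 0.5 mm with an optional
seasonal coupling of size to the pulse; per-chick logistic growth with
individual K deviations and Gaussian capture noise; day-by-day Bernoulli
survival from the logit-linear model on Gelman-standardized covariates (so
the interval likelihood is exercised against an honest day-level process);
relocations every 3 days with deaths observed at the next scheduled visit
and censoring at 21 days.

Default conditions mirror the study's scale: seven seasons, ~70-day
windows, two transects, 9 broods × 2 chicks per year (~126 radio-tagged
chicks), hatching around day 162 ± 4, K = 0.18 day⁻¹, Ti = 12 days,
A0 = 249 g, and survival coefficients chosen so roughly 20–25% of chicks
fledge. The `late_prey_size_config` scenario (eight seasons, 208 chicks)
makes the age × prey-size interaction dominant (β = 1.5), couples prey size
to the pulse, and varies pulse width as well as timing across years —
including years whose pulse is aligned with mid-development but too narrow
to cover late development, the regime in which a single-timepoint demand
model misreads exposure.

What the generator does **not** emulate: spatial structure and movement,
predator dynamics, sex-specific growth, radio failure, taxonomic structure
below order, multimodal resource pulses, and overdispersion beyond Poisson
counts. Passing recovery tests therefore demonstrate internal consistency
of the estimators under the stated model, not robustness to these real-data
complications.

## Problem sizes in the shipped tests and acceptance run

Chosen to keep a full run comfortably on one CPU: survival-recovery
coverage uses 50 seeded cohorts of 208 chicks sharing one resource draw
(coverage is over the survival process); growth-structure ranking uses 100
seeds × 100 chicks with a single optimizer start from the standard starting
values; trend coverage uses 100 seeds of a 9-year design; the demand-model
comparison uses 50 fully independent simulated studies; the acceptance
script runs the complete pipeline once on the default seven-season study.

## Known limitations

- The growth fitter's Laplace approximation is accurate for the small
  per-chick capture counts here but is not a substitute for adaptive
  Gaussian quadrature with many random effects per subject.
- cAIC uses a first-order (hat-trace) effective df; it ignores uncertainty
  in the variance components themselves.
- The Wald CIs of `fit_trend` carry no small-sample df correction; with few
  years they undercover slightly (the recovery test measures ~95% against a
  nominal 95% at 9 years).
- Inclusion probabilities from Kuo–Mallick selection depend on the slab
  width (Bartlett effect); compare them only across effects fitted with the
  same slab.
- `estimate_age_from_mass` ignores individual K deviations for unknown
  chicks and rounds to half-days, matching how field ages are recorded.
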