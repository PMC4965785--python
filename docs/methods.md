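# Methods

## Model and assumptions

The package estimates survivorship from a single cross-sectional sample
of ages, which is only valid under a stable age distribution: the
number of individuals observed at age x is proportional to
`λ^(-x) · l(x)`, where λ is the annual population growth rate and l(x)
the probability of surviving from birth to age x. By default λ = 1
(stationary population); the analysis cannot estimate λ from one
cross-section — growth and mortality are confounded — so sensitivity is
probed by refitting with `ln λ = -0.1`, which shifts the recovered
constant hazard by almost exactly +0.1 (the confound is algebraic:
`λ^(-x) e^(-a2 x) = e^(-(a2 - ln λ) x)`).

Mortality follows the Siler competing-hazard family: a declining
Gompertz maturation hazard `a1·e^(-b1 x)`, a constant baseline `a2`,
and a rising Gompertz senescence hazard `a3·e^(b3 x)`. The five
candidate models keep subsets of the three components. All parameters
are per-year rates; ages are continuous in the mathematics and integer
years (annuli counts) in the data.

Observed standardized frequencies are modelled as independent
homoscedastic normals around the expected frequency curve
`a · λ^(-x) · l(x)` with common residual SD σ. This is the observation
model the analysis tradition uses; its misspecification against real
sampling noise is discussed under Limitations.

## Data standardization

Tooth ages carry certainty codes A (highest), B (± about a year), C
(unusable); C records are dropped and B ages are used at their reported
integer value (no measurement-error model). Per-age proportions are
computed over tooth-aged records, pooled across sexes by default. When
a colony has unaged 0-year juveniles (pups captured but never
tooth-aged), the 0-class is forced to their observed capture proportion
p and the tooth-aged classes are rescaled to 1 − p; tooth-aged 0-year
records, if any, are subsumed into the forced class (with a warning),
since the observed capture proportion takes precedence. p = 1 with aged
records present is rejected as inconsistent. Only observed age classes
enter the likelihood; unobserved (zero-count) ages are not padded in.

## Priors

* amplitude `a` ~ U(0, m_a), with m_a defaulting to 10× the maximum
  observed frequency;
* residual SD σ ~ U(0, m_σ), with m_σ defaulting to 10× the SD of the
  observed frequencies;
* hazard parameters a1, a2, a3 ~ N(0, sd), untruncated;
* rate parameters b1, b3 ~ N(0, sd) truncated at 0.

The default sd is 0.1, i.e. the BUGS idiom `dnorm(0, 100)` read as
mean/precision. Two deliberate choices need explanation.

Untruncated amplitudes: on data with no maturation or senescence
signal, the posterior for a1 or a3 straddles zero. Truncating at zero
piles mass on the boundary and bends the posterior along curved ridges
(a1/b1 and a3/b3 trade-offs), which puts the posterior-mean plug-in far
off the ridge and drives the DIC complexity estimate pD strongly
negative — DIC becomes meaningless. With free amplitudes the posterior
mean of an unsupported component sits near zero and the plug-in is well
behaved. A negative amplitude describes regression curvature, not a
proper survivorship; demographic conversions (`SilerParams`,
`survivorship`, `results.to_params()`) still require non-negative
hazards, and `to_params()` clips small negative posterior means.

Confined rates: with a very flat prior (sd ≈ 100) the rate b of an
unsupported component is likelihood-free and its posterior spreads over
tens of units; the plug-in `exp(b̄ · age)` then overflows at any
realistic age span and DIC again degenerates, for every multi-component
model. sd = 0.1 keeps b within the range resolvable from integer-age
data. Rates are truncated at zero so each component keeps its identity
(declining juvenile hazard vs rising senescent hazard) and the sampler
does not face sign-swap multimodality.

## Sampling

Adaptive random-walk Metropolis on the active-parameter vector.
Proposals are multivariate normal; during adaptation the global scale
is tuned by Robbins–Monro toward 30% acceptance and the proposal
covariance is re-estimated from the accumulated history (Haario
scheme). Adaptation runs through an internal warm-up phase (default
2,000 iterations, discarded — the analogue of the adaptive phase BUGS
samplers run before recording) plus the burn-in fraction of the
recorded run, and is then frozen, so retained draws form a genuine
Markov chain. Defaults follow the standard protocol: 3 independent
chains, 10,000 recorded iterations, 10% burn-in, no thinning (a
`thin=10` comparison run agrees within Monte-Carlo error).

Starting values come from a brute-force least-squares grid search over
the expected-frequency curve (the `nls2` idiom), vectorized over the
product grid. The default grids include negative maturation/senescence
amplitudes so that all chains start in the global least-squares basin;
each chain is then jittered tightly around that point. Convergence is
monitored with classic split-R-hat per parameter; any value above 1.1
flags the fit as unconverged (reported, not fatal). Fits are
bit-reproducible given the config seed (chain seeds are spawned from a
`SeedSequence`).

## Model comparison

DIC = D̄ + pD with pD = D̄ − D(θ̄), deviance −2·log-likelihood
(likelihood only, priors excluded), θ̄ the posterior mean of the active
parameters. A model is "supported" only when it beats every competitor
by more than two DIC units; otherwise the working model is the most
parsimonious (fewest active hazard parameters) among those within two
units of the best, ties broken by lower DIC.

## Demographic summaries

Age-specific survival `S_x = l(x+1)/l(x)`; for the constant model
`S = exp(-a2)` per draw, summarized by the mean and equal-tailed 95%
interval. Life expectancy `-1/ln(S)` is computed from full-precision
posterior survival — note that `-1/ln(S)` applied to a *rounded* S
generally does not reproduce a life expectancy computed before
rounding. Because `-1/ln(S)` is convex in a2, the mean of per-draw life
expectancies exceeds the plug-in at the posterior-mean survival
(Jensen); the results object reports the plug-in, and the per-draw
version is available from the draws. Predicted age frequencies scale
the per-draw expected-frequency curve to colony size; the "maximum
plausible age" is operationalized as the first age at which the mean
expected count falls below one individual at the stated colony size.

## Covariate regression

Colony-level survival estimates are regressed on one covariate at a
time (population size, hunting-pressure rank in [0,1], proportion male)
by OLS via statsmodels, with the overall F-test on (1, n−2) degrees of
freedom. A precision-weighted variant (weights supplied per colony,
e.g. inverse squared CrI width) is available but off by default. A
constant response returns F = 0, p = 1.

## Synthetic colony generator

`simulate_colony` draws integer ages from the stable age distribution
implied by the chosen survivorship and growth rate (support extended
until the tail mass is below 1e-6; an error with guidance if the growth
tilt outpaces mortality). Capture bias is emulated by recording
`floor(p · n)` individuals as unaged 0-year juveniles (deterministic,
so fixture sizes are exact) and drawing the remaining ages conditioned
on age ≥ 1; sexes are Bernoulli(proportion_male). Sampling noise
arises naturally from the multinomial draw; an optional Gaussian
perturbation of the standardized frequencies (`noise_sd`, truncated at
zero, default 0) exists only to exercise the normal-error observation
model directly. The generator does not emulate migration between
colonies, seasonality, cause-specific (hunting vs natural) mortality,
or ageing error in the annuli counts.

## Problem sizes used by the tests and acceptance script

Recovery checks use 20 colonies of 1,500 captures at S = 0.86;
selection sweeps use constant colonies of 1,500 captures and
maturation+senescence colonies (a1=1, b1=1, a2=0.05, a3=0.005, b3=0.5)
of 5,000 captures — 20 replicates in the test suite, 12 in the
acceptance script; each fit is 3 chains × 10,000 iterations. The full
acceptance script runs in about two minutes on one CPU.

## Numerical choices

Gompertz terms switch to their analytic b → 0 limit (`l → e^(-a x)`)
below |b| < 1e-8; a component with zero amplitude is the constant 1
regardless of b. Likelihood evaluation guards against overflow
(non-finite expected frequencies yield log-likelihood −∞). The split
R-hat of a parameter with zero within-chain variance is defined as 1.
Degenerate chains (all draws identical) give pD = 0 exactly.

## Limitations

The normal-error observation model is doubly misspecified against
multinomial sampling of ages: class variances differ (young, abundant
classes are noisiest) and the sum-to-one constraint induces negative
correlations. Two measurable consequences, both growing with sample
size and the number of age classes:

1. Credible intervals for annual survival are too narrow at large n.
   At 1,500 captures (~40 age classes) the 95% CrI half-width is about
   0.008 while the true sampling SD of the estimate is about 0.006, so
   realized coverage is ~84% rather than 95%. Point estimates remain
   accurate (within ±0.03 of truth in every replicate tested).

2. DIC under-penalizes weakly identified components. Maturation's two
   extra parameters can absorb the high-variance young-age noise for a
   deviance gain of 1–3 units while pD charges well under one unit
   each, so on constant-hazard data at n = 1,500 a flexible model
   usually attains the lowest raw DIC. At realistic colony sample sizes
   (~100–150 captures) the effect is mild and the constant model wins
   about half the time or more; the two-unit-plus-parsimony selection
   rule still retains the constant model as the working model in most
   replicates at either scale. Conclusions should rest on the selection
   rule, not on raw lowest DIC, whenever candidate models are separated
   by less than two units.

Passing tests therefore demonstrate correct implementation of the
stated model and procedure, and honest behaviour of the pipeline on
data satisfying its assumptions — not robustness of the normal-error
likelihood to the sampling noise of real age-frequency data.
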