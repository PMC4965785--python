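# silersurv

Bayesian life-table analysis of tooth-cementum age-frequency data using
Siler competing-hazard survivorship models.

Wildlife demographers often cannot run capture–recapture studies on
long-lived, highly mobile species such as the straw-coloured fruit bat
(*Eidolon helvum*). What they can obtain is a cross-sectional sample of
ages — integer years counted from tooth-cementum annuli — from each
colony. If the population is at a stable age distribution, the shape of
that age-frequency curve carries the survivorship schedule, so annual
survival, life expectancy and the presence of juvenile (maturation) or
old-age (senescence) mortality can be estimated and compared across
colonies with different hunting pressure, population size and sex ratio.

## The model

Mortality is the sum of up to three competing hazards,

```
mu(x) = a1 * exp(-b1 * x)  +  a2  +  a3 * exp(b3 * x)
```

a declining Gompertz term for maturation, a constant baseline, and a
rising Gompertz term for senescence. Survivorship is the product of the
component survivorships

```
l1(x) = exp(-(a1/b1) * (1 - exp(-b1 x)))      # maturation
l2(x) = exp(-a2 x)                            # constant risk
l3(x) = exp( (a3/b3) * (1 - exp( b3 x)))      # senescence
```

and five candidate models keep different subsets: constant (l2),
maturation (l1·l2), senescence (l2·l3), maturation+senescence (l1·l3)
and the full Siler model (l1·l2·l3). Under population growth rate λ the
stable age distribution is proportional to `λ^(-x) · l(x)`; scaled by an
amplitude `a`, this is the expected age frequency. Standardized observed
frequencies `y_i` are modelled as `N(a · λ^(-x_i) · l(x_i), σ²)`,
fitted by MCMC (3 chains × 10,000 iterations, 10% burn-in), and the
five candidates are compared by DIC with the conventional two-unit
support rule. From the constant-risk fit, annual survival is
`S = exp(-a2)` and mean life expectancy is `-1/ln(S)`.

## Worked example

Simulate an Accra-like colony (1,500 captures, true annual survival
0.86), standardize it, and fit the constant-risk model:

```python
import silersurv as ss

_, data = ss.simulate_colony(
    ss.constant_scenario(0.86, 1500, seed=42, colony="accra-like")
)
res = ss.fit_model(data, ss.CONSTANT, config=ss.MCMCConfig(seed=1))
print(res.summary())
```

```
Siler survivorship fit: model CONSTANT, colony accra-like
ages: 43, draws: 27000 (3 chains), ln(lambda) = 0
DIC = -361.61  (Dbar = -364.46, pD = 2.86)
converged (all split-Rhat <= 1.1): True

        mean     sd   2.5%  97.5%   rhat
a     0.1414 0.0024 0.1367 0.1462 1.0003
a2    0.1542 0.0041 0.1461 0.1621 1.0007
sigma 0.0036 0.0004 0.0029 0.0045 1.0016
```

The amplitude `a` is the expected frequency at age 0, `a2` the constant
hazard, `sigma` the residual noise. Converting the posterior:

```python
s = res.annual_survival()
# S = 0.857 (95% CrI 0.850-0.864); truth was 0.86
print(res.life_expectancy())        # 6.48 years
pred = res.predict_age_frequencies(max_age=60, n_colony=100_000)
print(pred.max_predicted_age)       # 63: first age with < 1 expected bat
```

In a colony of 100,000 the fitted curve still predicts at least one
living individual up to age ~60 — the long tail typical of a low,
constant hazard. Model comparison and the covariate regression follow
the same pattern:

```python
fits = [ss.fit_model(data, m, config=ss.MCMCConfig(seed=1)) for m in ss.ALL_MODELS]
cmp = ss.select_model(fits)          # DIC table, two-unit rule, parsimony
ss.ols_fit(proportion_male, survival_estimates)  # F-test on the slope
```

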