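# odscox — weighted Cox regression for outcome-dependently sampled survival data

Study cohorts in genetic epidemiology are rarely random samples. Families are
recruited through clinical genetic testing when a member is diagnosed young,
so the resulting samples over-represent events and short lifetimes. Fitting an
ordinary Cox proportional hazards model `h(t|z) = h0(t) exp(βz)` to such a
sample attenuates the estimated log-hazard ratio β, because the selection
distorts the joint distribution of age-at-onset and covariate.

`odscox` corrects this by inverse-probability-of-selection weighting against
an external registry: population incidence rates μ_k on age intervals
I_k = [a_{k−1}, a_k), from which the interval survival is
S_k = exp(−μ_k (a_k − a_{k−1})). Two per-interval weighting schemes are
implemented, and β is then estimated from the weighted partial-likelihood
score with Huber–White sandwich standard errors:

- **Traditional weighted-cohort**: events in I_k get weight w_k and censored
  subjects v_k, solving the constraint that the weighted sample incidence rate
  equals μ_k in every interval while each interval's mean weight stays 1.
  Valid only when every age group contains both events and censorings and
  events are sufficiently oversampled; the four validity conditions are
  checked and reported, never silently repaired.
- **Generalized weighted-cohort**: censored subjects stay unweighted
  (v_k = 1) and events get
  `w_k = [(1 − S_k)/S_k] · [S_k^o/(1 − S_k^o)]`,
  where S_k^o is the observed conditional survival through I_k. This rescales
  the event/non-event ratio of each risk set to the population ratio, stays
  strictly positive under arbitrary over- or under-sampling of events, and
  needs no censoring anywhere. Under representative sampling all w_k = 1 and
  the estimator reduces to unweighted Cox regression.

The package also ships a shared gamma-frailty Cox fitter (EM / profile
likelihood) as a sensitivity analysis for unobserved within-family
heterogeneity, a family-based ascertainment simulator, and a Monte Carlo
driver that evaluates relative bias, MSE, CI coverage and the proportion of
invalid traditional weights across scenarios.

## Worked example

Simulate a registry (200,000 unselected singletons), estimate its interval
rates, draw a strongly ascertained sample (families of two, kept only if a
member has an event younger than the population's first quartile), and
compare the naive and weighted fits when the true log-hazard ratio is β = 1:

```python
import numpy as np
from odscox import (SimConfig, IPSWeightedCoxPH, WeightedCoxPH, surv_array,
                    simulate_reference_population, estimate_reference_rates,
                    simulate_ascertained_sample)

ref = simulate_reference_population(200_000, beta=1.0, seed=42)
table = estimate_reference_rates(ref, np.arange(0, 120, 20.0))

sample, n_inc = simulate_ascertained_sample(
    SimConfig(n_families=750, family_size=2, n_affected_required=1,
              beta=1.0, seed=42))

X = sample[["covariate"]].to_numpy()
y = surv_array(sample["status"], sample["time"])
naive = WeightedCoxPH().fit(X, y).result()
gen = IPSWeightedCoxPH(intervals=table, right_closed_last=True).fit(X, y).result()
for r in (naive, gen):
    print(f"{r.method:12s} beta_hat={r.beta_hat:.3f}  "
          f"95% CI ({r.ci_low:.3f}, {r.ci_high:.3f})")
```

```
unweighted   beta_hat=0.778  95% CI (0.682, 0.873)
generalized  beta_hat=0.977  95% CI (0.861, 1.093)
```

The ascertained sample keeps 331 of 750 families (86% of included subjects
are events); the naive estimate is attenuated by ~22% while the generalized
weighted estimate recovers the true β = 1 within its confidence interval.

The estimators follow scikit-learn conventions (`fit` / `predict`,
`get_params`, fitted attributes like `coef_`, `se_robust_`), so they compose
with sklearn tooling; `fit_cox`, `fit_weighted_cox` and `fit_shared_frailty`
are one-line wrappers for subject DataFrames.

## Command line

The same workflow is available on CSV files (subjects:
`family_id,time,status,covariate`; rates: `age_low,age_high,rate`):

```sh
odscox simulate --scenario A3 --n-families 750 --beta 1 --seed 42 \
       --with-reference-rates --out data/
odscox weights data/subjects.csv --intervals data/rates.csv \
       --scheme generalized --out weights/ --right-closed-last
odscox fit data/subjects.csv --intervals data/rates.csv \
       --method generalized --out fit.json --right-closed-last
odscox study --scenario A3 --n-families 250 --beta 0.3 --censor-mean 60 \
       --trials 100 --seed 1 --out study.csv
```

`odscox fit --method traditional` exits nonzero with a clear message when the
traditional scheme produces invalid (negative) weights — the practical
situation the generalized scheme was designed to survive.

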