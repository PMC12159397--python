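# Methods

## Setting and model

We observe n individuals in N families, each contributing an age
t_ij = min(T_ij, C_ij) measured from birth (no left truncation), an event
indicator δ_ij, and a covariate z_ij. The target of inference is the
log-hazard ratio β of the proportional-hazards model
h(t|z) = h0(t) exp(βz) in a reference population of interest. The sample,
however, is collected under family-based outcome-dependent selection:
families enter the study only when enough members are affected, typically
including someone affected young. Selection is assumed to depend on the
observed ages only — conditionally independent of the covariate given the
event times — which is what makes inverse-probability-of-selection weighting
identifiable from external age-specific incidence rates alone.

External information enters as a grid of K age intervals
I_k = [a_{k−1}, a_k) with population incidence rates μ_k (events per
person-year). Two working assumptions are inherited from this discretization:
hazards are constant within each interval, so the conditional probability of
passing through I_k event-free is S_k = exp(−μ_k (a_k − a_{k−1})); and
right-censoring is discrete, occurring at interval endpoints. Violations of
the second assumption (random censoring inside intervals) are the main source
of residual bias; see "Estimating S_k^o" below.

## Weighting schemes

**Traditional weighted-cohort.** All r_k events in I_k receive weight w_k and
all s_k censored subjects weight v_k such that (i) the weighted sample
incidence rate in I_k equals μ_k, and (ii) the average weight in each
interval is one. Solving the two equations gives the closed form

    w_k = μ_k (q_k (r_k + s_k) + (a_k − a_{k−1}) s_k Σ_{l>k}(r_l + s_l))
          ───────────────────────────────────────────────────────────────
          r_k s_k + μ_k (q_k r_k − p_k s_k)

    v_k = (r_k + s_k − w_k r_k) / s_k ,

where p_k and q_k are the person-times accrued *inside* I_k by its events and
censored subjects (t_ij − a_{k−1}; subjects who outlive the interval
contribute the full width through the tail sum, which is why within-interval
exposure is the dimensionally consistent choice — the raw-age variant is
available as `person_time="age"`). The mean-one constraint implies the
weighted tail Σ_{l>k}(v_l s_l + w_l r_l) equals the raw count
Σ_{l>k}(r_l + s_l), so each interval's weights are computable independently.

Validity requires, in every interval where a weight is actually used:
censored subjects present when there are events (condition 8 — otherwise
w_k is undetermined, which is why the scheme fails entirely on samples
without censoring), a positive denominator (condition 9, guaranteed under
genuine oversampling of events), and w_k < 1 + s_k/r_k (condition 10 —
otherwise v_k < 0). An interval without events needs no case weight and its
v_k = 1 solves the mean-one constraint exactly, so it is not counted as a
failure by default; `require_all_intervals=True` restores the textbook
preconditions that also demand events everywhere. Invalid weight sets are
returned with a per-interval violation report — the Monte Carlo driver counts
them, and the fitting layer refuses them; no automatic interval merging is
attempted.

**Generalized weighted-cohort.** Decomposing the N_k subjects at risk at
a_{k−1} into those with events in I_k and those surviving it, the reference
population's event/non-event ratio is (1 − S_k)/S_k while the sample's is
(1 − S_k^o)/S_k^o. Keeping non-events unweighted (v_k = 1) and setting

    w_k = [(1 − S_k)/S_k] · [S_k^o/(1 − S_k^o)]

makes the weighted risk-set composition match the reference in every
interval. The weights are strictly positive whenever events are observed
(w_k < 1 under oversampling, w_k > 1 under undersampling, w_k = 1 under
random sampling, where the method collapses to unweighted Cox regression).
Only S_K > 0 is additionally required — automatic for defective event-time
distributions such as age at cancer diagnosis. Intervals without events have
nothing to reweight; their placeholder w_k = 1 is never used (`strict=True`
raises instead).

**Estimating S_k^o.** When censoring respects interval endpoints,
S_k^o = (N_k − r_k)/N_k. Under random censoring inside intervals that
estimator overstates survival (censored subjects are counted as survivors of
the interval), which propagates into the weights; the default is therefore
the Kaplan–Meier estimate of the conditional survival through I_k, which
removes censored subjects from the risk set at their censoring times and
reduces exactly to (N_k − r_k)/N_k in the endpoint-censoring case. The
endpoint and actuarial (N_k − s_k/2) variants are available via
`s_obs_method`. In simulations with within-interval censoring the KM choice
keeps the generalized estimator's CI coverage near nominal where the endpoint
variant loses ~10 coverage points.

## Estimation and variance

β solves the weighted partial-likelihood score (Breslow ties),

    U(β) = Σ_{ij: δ=1} W_ij [ z_ij − Σ_{l∈R(t_ij)} W_l z_l e^{βz_l}
                                     / Σ_{l∈R(t_ij)} W_l e^{βz_l} ] = 0 ,

with risk sets R(t) = {l : t ≤ t_l} and per-subject weights W_ij assigned by
interval and status. A variant that weights only the risk-set sums (not the
event terms) is available (`weight_events=False`); both are consistent under
the conditional-independence assumption and agree closely in practice, and
the weighted-event form is the convention of the weighted-cohort literature.
The solver is a Newton–Raphson with step-halving (start β = 0, convergence
|Δβ| < 1e−9, max 50 iterations), fully vectorized via suffix cumulative sums
over the time-ordered sample, so one fit costs O(n log n); monotone
likelihoods (separation) are detected via exploding coefficients on the
standardized covariate scale and flagged rather than reported as converged.

Standard errors: the inverse observed information for unweighted fits; the
Huber–White sandwich A⁻¹BA⁻¹ for weighted fits, with B built from per-subject
weighted score residuals (optionally summed within families via
`cluster_by="group"`). The weights are treated as fixed — the variability of
estimating them from the sample is ignored, a known mild anticonservatism of
this construction. 95% CIs use the normal approximation.

**Shared gamma frailty.** As a sensitivity analysis, a Cox model with a
family-shared multiplicative frailty u_j ~ Gamma(mean 1, variance θ) is
fitted by the classical EM (posterior frailty means (1/θ + D_j)/(1/θ + Λ_j),
M-step Cox fit with log-frailty offsets, Breslow baseline), with θ maximizing
the profile of the marginal likelihood over a bounded log-grid
(θ ∈ [1e−5, 20], golden-section). Estimates squeezed against the lower bound
are flagged as boundary solutions; samples where every family has one member
cannot identify θ and are flagged. The reported SE is the conditional one at
the converged frailty offsets; it understates the extra uncertainty in θ, so
the frailty variance itself should be read qualitatively. Weighted frailty
fitting is deliberately not offered: with unobserved heterogeneity the
selection is no longer independent of the event times given the covariate, so
the weights' premise fails.

## Synthetic data

The simulator emulates recruitment through clinical genetic testing:

- Event times: T ~ Exponential with hazard u_j λ0 e^{βz}, λ0 = 1/60 per year
  (mean 60 years at baseline — a plausible scale for adult-onset cancer in a
  high-risk population), z ~ N(0,1) iid across family members, optional
  family-shared gamma frailty u_j (mean 1, variance θ).
- Censoring: optional random censoring C ~ Exponential(mean 60 or 40 years),
  then administrative censoring at 100 years. "Medium" censoring yields ~44%
  censored included observations, "high" ~51%.
- Ascertainment: N families of fixed size n_j (5 or 2) are generated; a
  family is included iff at least n_A members have an observed event *and* at
  least one affected member is "young" — observed event age below the first
  quartile of the observed-age distribution of the trial's own
  pre-selection sample. (A variant computes the cutoff from the latent
  event-time distribution of a matched reference; the observed-age rule is
  the default because it calibrates the inclusion fraction identically across
  censoring regimes.) Scenario labels: A1 (n_j=5, n_A=1, mild), A2 (5, 3,
  medium), A3 (2, 1, strong).
- Reference population: 200,000 unselected singletons with the same (β, θ);
  interval rates are the piecewise-exponential MLE, events divided by
  within-interval person-years.

What the simulator does **not** emulate: pedigree structure beyond a flat
family, within-family covariate correlation, proband right-truncation,
competing risks, or time-varying covariates. Passing tests therefore
demonstrate correction of outcome-dependent selection under these idealized
conditions, not robustness to every feature of real clinical-genetics data.

## Monte Carlo evaluation

For each scenario the driver runs M trials; each sample is analysed by the
unweighted, traditional-weighted and generalized-weighted fits (and
optionally the frailty model). Reference rates are estimated once per
configuration and shared by all its trials. In frailty scenarios the default
weights are built from a frailty-*blind* reference (same β, θ = 0): registry
rates are modelled without familial random effects, and quantifying the
resulting noncollapsibility bias is the purpose of the sensitivity setting; a
frailty-matched reference is available via `reference_frailty_var`.

Reported per (scenario, method): relative bias (mean β̂ − β)/β — plain bias
when β = 0 — MSE, coverage of the nominal 95% CI, the proportion of trials
with invalid traditional weights, and mean included-family counts and
censoring percentages. Every summary carries its Monte Carlo standard error;
trials where a method fails (invalid weights, non-convergence) are excluded
from that method's summaries and counted in `n_effective`. Randomness is
controlled by a single base seed; trial m of a scenario uses an independent
child stream derived from (base_seed, m), so studies are reproducible and
trials are independent.

The acceptance script runs each of its cells at M = 1000 trials with a
200,000-subject reference — the full study size, which completes in well
under a minute per cell thanks to the vectorized solver. The test suite
exercises the same cells at M = 150–300 with correspondingly wider
(3 Monte Carlo SE) bands.

## Numerical notes and edge cases

- Interval membership is half-open [a_{k−1}, a_k); a time equal to the last
  break a_K is rejected unless `right_closed_last=True`, which the simulation
  pipeline sets because administrative censoring lands exactly on the grid
  end. Within aggregation, tied times are handled by the usual convention
  that events precede censorings.
- The partial-likelihood solver guards exponential overflow by shifting the
  linear predictor (the shift cancels exactly in every term), and declares
  separation when |β|·sd(z) exceeds 50.
- Weight sets are plain per-interval vectors; exporting them (CSV) records
  interval bounds, w_k, v_k, per-interval validity and violated conditions.
- Degenerate inputs that are reported rather than repaired: empty risk sets
  mid-grid (internal inconsistency), event-free intervals (unused weight),
  samples with no events (no partial likelihood), nonpositive per-subject
  weights (refused by the fitter), near-degenerate grids with
  (1 − S_k)/S_k > 1e6 (logged warning).
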