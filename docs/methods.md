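# Methods

`profilesim` simulates provider-profiling exercises — classifying health-care
providers as performing normally or as outliers on risk-adjusted mortality —
and measures how accurately six risk-adjustment methods recover the true
outlier status. This note documents the generating model, the estimators, the
numerical choices, and what the synthetic design does and does not represent.

## Data-generating model

**Case-mix.** Each patient carries eight predictors of post-CABG mortality:
centered age (years) and seven binary risk factors (female sex, chronic
pulmonary disease, extracardiac arteriopathy, unstable angina, moderate LV
dysfunction, recent myocardial infarction, emergency intervention). The
generator is parametric: age ~ Normal(0, 10²) truncated at ±30 years, binaries
~ Bernoulli with configurable prevalences, independent by default with an
opt-in latent-Gaussian copula. The default prevalences (25% female, 10%
chronic pulmonary disease, 11% extracardiac arteriopathy, 15% unstable angina,
25% moderate LV dysfunction, 10% recent MI, 6% emergency) are **synthetic
stand-ins** chosen as plausible isolated-CABG values; all exceed the 5%
inclusion floor used to select case-mix variables from cardiac-surgery
registries. Real registries exhibit correlations among these factors and
skewed age distributions that this generator does not emulate, so accuracy
levels measured here characterize the design, not any particular registry.

**Attendance (confounding).** Patient *i* attends provider *k* ∈ {1..K} with
multinomial-logit probability
π_k ∝ exp(α_k + β_k·(Z1+…+Z8)), with α_k = 0, β_1 = 0 (reference), and
β_k ~ Uniform(0,1) shared across the eight predictors for k ≥ 2. Providers
with larger β attract sicker patients, confounding crude comparisons. Fixed
per-provider volumes are met by rejection: a fresh candidate is drawn, one
provider is drawn from its π vector, and the candidate is discarded entirely
when that provider is full. This conditions the tail of each quota slightly
(the last patients of a nearly-full design are drawn conditionally on choosing
the unfilled providers), which is inherent to the quota rule. Intercepts are
fixed at zero because quotas, not intercepts, determine realized volumes; a
1000·N draw cap guards pathological configurations.

**Outcomes.** Mortality follows a random-intercept logistic model
logit(p_ik) = γ00 + α0k + Σ β′_j Z_j, with α0k ~ N(μ_k, σ²), σ = 0.1942,
μ_k = 0 for normal providers and ±H·σ for true outliers (positive = excess
mortality = below-average performance; one-sided designs put all outliers on
that side). The case-mix coefficients β′ default to the published logistic
EuroSCORE values for these eight predictors, with age entered as a centered
per-year log-odds term (the original model codes age in years above 60; only
the slope matters here since the intercept is recalibrated, and the coding is
fully overridable). γ00 is calibrated per generated dataset by Brent root
finding so the realized-sample mean of p_ik equals the scenario's target
incidence to < 1e-6 — calibration on the realized sample, not in expectation,
guarantees the stated average incidence for every dataset. Every provider must
realize ≥ 1% incidence; violations trigger up to 100 outcome redraws at the
same probabilities, then a redraw of the random intercepts with recalibration
(the least-perturbing enforcement consistent with the constraint).

## The six methods

* **LR_F** — stage 1: logistic regression of y on case-mix only, keeping the
  intercept γ̂; stage 2: logistic regression on K provider dummies (no
  intercept) plus case-mix. A provider is an outlier when its 95% Wald CI
  excludes γ̂ (γ̂ treated as a known constant; no uncertainty propagation).
* **LR_R** — random-intercept logistic regression with the eight case-mix
  fixed effects; a provider is an outlier when its empirical-Bayes deviation
  exceeds 2·σ̂.
* **gPS_A** — as LR_R with K−1 generalized propensity scores (multinomial
  logistic fitted probabilities of attendance; the reference provider's
  column dropped for linear dependence) entered linearly as fixed effects.
* **gPS_W / gPS_WT** — inverse weighting by the gPS of the attended provider
  (gPS_WT trims weights above the 98th percentile to that percentile),
  followed by a weighted providers-only random-intercept fit and the 2·σ̂
  rule.
* **gPS_MWS** — marginal mean weighting through stratification: quintile
  strata on each provider's gPS over the whole sample; weight = stratum size ×
  marginal attendance share ÷ stratum attendees; then as gPS_W.
  Common-support trimming is deliberately omitted (with many providers it
  empties the sample), which is part of what the comparison measures.

"Two observed standard deviations" is read as the model-estimated
random-intercept SD σ̂ (default); the empirical SD of the EB deviations is
available via `rule="eb_sd"`. The default satisfies the rare-outcome bounds
this package reproduces, while `eb_sd` — being smaller under shrinkage —
flags more eagerly and breaks them; see Limitations for the consequence at
high outlier fractions.

## The mixed-model engine

No installed Python library fits a *weighted* random-intercept logistic GLMM,
so the engine is implemented here. The marginal likelihood integrates the
scalar random intercept per provider by adaptive Gauss–Hermite quadrature
(default 15 nodes, recentered at each group's posterior mode and rescaled by
its curvature; Newton inner iterations with step clipping). The outer
L-BFGS-B optimization runs on (β, log σ) with gradient tolerance 1e-8,
σ bounded in [1e-4, 10], and an automatic restart from a neutral σ when a
line search aborts. Gradients are exact marginal-likelihood scores obtained
from Fisher's identity (posterior expectation of the complete-data score)
evaluated on the same quadrature nodes. Initialization: IRLS logistic
regression for β and a method-of-moments value for σ. Standard errors, when
requested, come from the numerically differentiated observed information.

Weights are frequency-type multipliers of log-likelihood contributions (the
`glmer` convention). Unlike a plain GLM, rescaling all weights by a constant
is *not* exactly neutral for the fixed effects, because the random-effect
prior does not scale with the likelihood: point estimates shift slightly
(≈0.007 log-odds at a 10× rescale in testing) and σ̂ changes visibly. This
matches `lme4::glmer` behaviour and matters when comparing raw-IPW fits
(total weight ≈ N·K) with unit-weight fits.

Two numerical conveniences do not change results: observations are sorted by
provider for contiguous reductions, and covariate blocks entering GLMM-based
classifiers are replaced by orthonormalized (QR) factors — σ̂, the EB
deviations and the log-likelihood are invariant to invertible linear maps of
the fixed-effects block, and conditioning cuts optimizer iterations several
fold, especially for gPS_A whose near-compositional score columns are
otherwise badly conditioned. The weighted providers-only fits collapse each
provider to two weighted pseudo-observations (events / non-events), which
leaves the weighted likelihood identical.

Quantiles everywhere (weight trimming, MMWS quintiles, percentile intervals)
are numpy's linear-interpolation sample quantiles, fixed for bit
reproducibility.

## Accuracy measures

Per replicate, observed labels are compared with true status at the provider
level with *outlier* as the positive class and direction ignored. Sensitivity,
specificity, PPV and NPV are averaged over replicates where defined — an
empty denominator (e.g. PPV with no flags) is recorded as missing and
excluded, never as zero, with exclusion counts reported; eagerness (the
fraction of replicates with at least one flag) separately captures the
no-flag behaviour. Intervals are 5th/95th percentiles of the per-replicate
values. Method failures (separation, non-convergence) drop that method for
that replicate and are counted.

## Scenario grid and problem sizes

Seven one-parameter sweeps around the baseline (K=50, p̄=0.10, 20% outliers,
H=2, two-sided, volumes 1000, P(nmin)=0.5): K ∈ {10..50}, p̄ ∈
{0.03, 0.10, 0.20}, outlier fraction ∈ {0.08, 0.20, 0.40}, H ∈ {1..4}, sides
∈ {1, 2}, min volume ∈ {500, 1000}, P(nmin) ∈ {0.5, 1}. Replicate seeds
derive injectively from (master seed, scenario, design point, replicate), so
any execution order or resumed run reproduces identical outputs.

The package's own reproduction runs at desk scale: 100 replicates (400 for
the rare-outcome bounds, whose margins are tail-sensitive) and K = 10–30
providers of 1000 patients, chosen because the reproduced quantities are
stable in K at these levels while a full 1000-replicate, K=50 grid is a
cluster-scale exercise. The accompanying summaries use a ±10-percentage-point
band for "approximately"-qualified levels, which comfortably covers the
Monte-Carlo error at these sizes.

## Known limitations

* The case-mix generator is a labeled stand-in; passing accuracy checks here
  demonstrates properties of the *design*, not of any empirical registry.
* Sensitivity of the shrinkage methods at small K is conservative: with K=10
  and a 40% outlier fraction, σ̂ is strongly inflated by the outliers
  themselves, and the measured common sensitivity level (~2%) sits below the
  ~7% seen at K=50 where 20 outliers stabilize the threshold.
* gPS and outcome models are always correctly specified and share the same
  covariates; misspecification, unmeasured confounding, balance diagnostics,
  gPS matching and plain gPS stratification are out of scope.
* The quota-rejection rule redraws the whole patient when the drawn provider
  is full; redrawing only the provider would be an alternative reading of the
  same informal description.
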