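# Methods

## Model

Individuals `i` are nested in intersectional strata `s`, the cells of the full
cross-classification of five categorical social dimensions (gender 2, race/
ethnicity 3, schooling 4, family income 4, public-health-system use 2; 192
cells). Two random-intercept logistic models are fitted by maximum likelihood:

1. **Null:** `logit P(y_is=1) = β0 + u_s`, `u_s ~ N(0, σ²_u)`;
2. **Full:** `logit P(y_is=1) = x'_s β + u_s`, where `x_s` treatment-codes the
   five dimensions (references: man, Black or Brown, no schooling, low income,
   public-system user).

Assumptions: stratum effects are exchangeable draws from a single normal
distribution on the log-odds scale; observations are independent given their
stratum; covariates are constant within a stratum by construction (they define
it), which the implementation exploits by collapsing records to per-stratum
binomial counts before any likelihood evaluation.

## Estimation

The marginal likelihood integrates each stratum effect against its normal
prior. Each one-dimensional integral is evaluated by **adaptive Gauss–Hermite
quadrature**: nodes are recentred at the stratum's posterior mode and rescaled
by the curvature there (damped Newton on a strictly concave objective), then a
standard Gauss–Hermite rule is applied in log-space. Default 15 nodes; the
log-likelihood changes by < 1e-6 between 15 and 25 nodes on all test fixtures,
and agrees with dense trapezoid integration to ~1e-13 on small fixtures and
with `lme4::glmer` (nAGQ = 15) to ~1e-3 on coefficients and ~1e-4 on the
log-likelihood in a cross-check test.

Optimization is quasi-Newton (L-BFGS-B) over `(β, log σ_u)` with the variance
parameterized on the log-sd scale and bounded below (`log σ_u ≥ −7`); an
estimate pinned at the bound is reported as a boundary fit with `σ²_u = 0`.
Convergence tolerances: relative objective change 1e-12, projected gradient
1e-6. The objective trace is monotone (line-search safeguard) and recorded.
Standard errors come from the numerically differentiated observed information
(central differences, relative step 1e-4); when the variance sits at its
boundary or is fixed, only the β block is differentiated. At `σ²_u = 0` the
likelihood reduces exactly to ordinary logistic regression (verified against
statsmodels to 1e-5), and `fit_glmm(..., FitOptions(fix_sigma_u2=0.0))`
exposes that limit directly. Very large coefficient magnitudes (>10) raise a
complete-separation warning rather than failing.

**Empirical-Bayes stratum effects** are posterior modes (conditional modes,
the mixed-model convention), with spread taken from the curvature at the mode.
Strata with no records receive the prior-only prediction (mode 0, sd σ_u) and
are flagged. Shrinkage toward zero grows as stratum size falls; strata with
all-0 or all-1 outcomes remain finite through the prior.

## Derived statistics

* **VPC** uses the latent-response convention with the level-1 residual fixed
  at 3.29 (π²/3 to the precision conventionally quoted): `σ²_u/(σ²_u+3.29)`,
  reported in percent.
* **PCV** `= (σ²_null − σ²_full)/σ²_null` in percent; its complement is
  reported alongside as the share of between-stratum variance attributable to
  intersectional interactions. PCV is undefined (explicit error) when the
  null-model variance is zero.
* **AUC**: individuals are scored with their stratum's predicted probability
  (intercept or fixed effects plus the EB deviation); the AUC is the
  Mann–Whitney concordance with midrank tie handling — ties are pervasive
  because scores are constant within stratum, so the ½-credit convention is
  load-bearing, not cosmetic.
* **Decomposition**: `p_total = logit⁻¹(x'β̂ + û_s)`,
  `p_additive = logit⁻¹(x'β̂)`, interaction = difference (percent scale, exact
  by construction). The *full* model supplies the decomposition because the
  additive component is defined by its fixed effects; null-model probabilities
  `logit⁻¹(β̂0 + û_s,null)` are carried in parallel for ranking, extremes
  tables and caterpillar exports, which conventionally use the null model.
* **Interval estimates** for stratum probabilities use parametric simulation
  (the model does not yield closed-form CIs for `logit⁻¹` of a sum of
  estimates): β is drawn from its asymptotic normal (eigenvalue-clipped
  factorization of the estimated covariance), `u_s` from its EB normal
  approximation, B = 1000 draws by default, percentile bands, fully seeded.
  Bands are widened to include the point estimate in the rare draw-sparse
  case. A simulation test shows ≥ 88% empirical coverage of true stratum
  probabilities. B < 100 triggers a warning.

Wald coverage of the fixed effects runs slightly below nominal (~89–90% at
n = 5000 with ~150 observed strata): ML underestimates the random-effect
variance in modest samples and the Wald intervals ignore that uncertainty — a
known property of ML GLMM inference, documented rather than corrected.

## Synthetic data generator

The generator emulates the default study's conditions: categories drawn
independently per dimension from the published marginal frequencies
(renormalized over analytic categories); additive log-odds equal to the logs
of the published odds ratios with intercept ln 0.19; a per-cell deviation
`u_s ~ N(0, σ²_int)` drawn for *all* 192 cells (so rare cells behave
realistically) plus optional explicit per-cell offsets; Bernoulli outcomes;
and item non-response applied last (gender 1.9%, income 6.6%, outcome 0.9% by
default, jointly ≈ 9% incomplete records — matching the default survey's
non-analytic response shares). The default interaction variance is 0.033,
sized so the full-model VPC sits near 1%. Four independent RNG streams
(deviations, categories, outcomes, missingness) are spawned from one seed, so
the truth table reproduces the exact realized deviations of a generated
cohort.

What the generator does **not** emulate: real association between dimensions
(they are sampled independently; an optional log-linear schooling–income tilt
exists for stress tests, default off), geography and interviewer effects,
temporal drift, and informative missingness. Passing tests therefore
demonstrate that the estimation and decomposition machinery recovers known
generative truth under the study's marginal structure — not that any
particular real-world dataset satisfies the model.

## Design choices

* **Digit-coded stratum IDs**: one digit per dimension, 1-based position in
  the analytic category order (man=1/woman=2; White=1/Black or Brown=2/
  other=3; schooling none→higher = 1→4; income low→high = 1→4; public-system
  yes=1/no=2). IDs are a bijection with category tuples; unobserved cells are
  materialized with `n_obs = 0` so predictions can flag them.
* **Race/ethnicity reference** is Black or Brown (the largest group), so the
  full model reports ORs for White and Other relative to it.
* **Complete-case filtering** treats designated non-analytic responses
  ("No answer", "Did not know") as missing; which variables are key is part of
  the codebook, not hard-coded, since different surveys draw the line
  differently.
* **Rounding**: descriptive percentages half-up to one decimal (survey-table
  convention); Cochran sizes always ceil, with the finite-population
  correction applied to the unrounded infinite-population size.
* **Problem sizes in tests**: oracle fixtures ≤ 200 observations; recovery
  and coverage suites use 100 replicates at n = 5000 and 20 replicates at
  n = 4000; the additive-mechanism checks use single n = 20 000 cohorts —
  sizes at which collapsed-likelihood fits take well under a second each.

## Known limitations

Single random intercept only (no random slopes, crossed effects, or
non-logit links); no survey weights or imputation; Wald/EB-based intervals
(no bootstrap or MCMC); the PCV is a point estimate without an uncertainty
band; boundary variance estimates make the PCV saturate at 100% in small
samples even when the generative interaction variance is positive but small.
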