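# maihda

Intersectional **MAIHDA** — *multilevel analysis of individual heterogeneity
and discriminatory accuracy* — for binary survey outcomes, as a tested Python
library with a thin command-line pipeline.

## What problem this solves

Health and social surveys often ask how an outcome (here: whether a person
sought COVID-19 information online) varies across intersecting social
positions — gender × race/ethnicity × schooling × income × public-health-system
use. Analyzing each dimension separately hides how disadvantage accumulates and
whether specific *combinations* carry effects beyond the sum of their parts.
MAIHDA answers this by nesting individuals in the full cross-classification of
their social dimensions (the *intersectional strata*; with category counts
2, 3, 4, 4 and 2 that is 2×3×4×4×2 = 192 cells) and fitting two
random-intercept logistic models:

* **Model 1 (null):** `logit P(y_is = 1) = β0 + u_s`, with stratum effects
  `u_s ~ N(0, σ²_u)`. The between-stratum variance measures total
  intersectional inequality.
* **Model 2 (full):** adds additive main effects of every dimension,
  `logit P(y_is = 1) = x'_s β + u_s`. What remains of σ²_u is inequality that
  additive effects cannot explain — intersectional interaction.

Derived statistics:

* **VPC** (variance partition coefficient, latent scale):
  `σ²_u / (σ²_u + π²/3)`, with the logistic residual fixed at 3.29;
* **PCV** (proportional change in variance):
  `(σ²_u,null − σ²_u,full) / σ²_u,null`; its complement indexes residual
  interaction;
* **AUC** of stratum-based predicted probabilities (tie-corrected
  Mann–Whitney) — the strata's discriminatory accuracy;
* per-stratum predicted probabilities with an exact **additive/interaction
  decomposition**: `p_total = logit⁻¹(x'β + û_s)` versus
  `p_additive = logit⁻¹(x'β)`, where `û_s` is the empirical-Bayes (posterior
  mode) stratum deviation;
* rankings, top/bottom strata, and caterpillar-plot exports.

Estimation is by maximum likelihood with an **adaptive Gauss–Hermite
quadrature** marginal likelihood written for this package (default 15 nodes;
it matches R's `lme4::glmer` at the same quadrature order to ~1e-6). A seeded
synthetic-data generator reproduces the default study's conditions — published
marginal frequencies, published additive odds ratios, a controllable
between-stratum interaction variance and realistic item non-response — so the
entire pipeline is testable without microdata.

## Worked example

```bash
python examples/run_full_analysis.py
```

generates a 2652-record synthetic cohort at the default study conditions,
filters incomplete records, and runs the two-model workflow. It prints:

```
observed strata          : 122 of 192
VPC null / full model    : 17.8% / 0.0%
PCV                      : 100.0%  (complement 0.0% = residual interaction)
AUC null / full model    : 0.72 / 0.70
```

Read: about 18% of the latent-scale variance in information seeking lies
*between* intersectional strata (substantial inequality); adding the five
additive main effects absorbs essentially all of it (PCV ≈ 100%), so the
inequality is cumulative rather than synergistic; the strata discriminate
individuals with AUC ≈ 0.72. The script then prints the fixed-effect odds
ratios (women ≈ 1.5, higher education ≈ 4–6, higher income ≈ 2.5–6 relative to
their reference groups) and the five least/most likely strata — the lowest
probabilities concentrate among men with no schooling and low income, the
highest among women and the higher-schooling, higher-income cells, spanning
roughly 16% to 79%.

Other examples: `sample_size.py` (Cochran design minimum, 385 at z=1.96,
ε=0.05, p=0.5), `simulate_cohort.py` (generator + complete-case accounting),
`interaction_detection.py` (an injected +1.0 log-odds cell is recovered as the
top interaction stratum), `caterpillar_plot.py` (ranked probabilities figure).

The same pipeline is available from the shell:

```bash
maihda simulate --n 2652 --seed 1 --output-dir sim/
maihda analyze --input sim/cohort.csv --output-dir out/
maihda samplesize --epsilon 0.05
```

## Layout

```
src/maihda/
  cohort.py     codebook, CSV ingestion, complete-case filter, descriptives, Cochran
  strata.py     cross-classification schema, digit-coded stratum IDs
  glmm.py       adaptive-quadrature GLMM: likelihood, ML fit, EB prediction, Wald ORs
  stats.py      VPC, PCV, AUC, decomposition, CIs, rankings, run_maihda
  synthetic.py  seeded generator + per-cell truth table
  cli.py        thin click CLI (simulate / analyze / describe / samplesize)
  defaults.py   the default survey's codebook, marginals and effect sizes
```

See `docs/methods.md` for the statistical details and design choices.
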