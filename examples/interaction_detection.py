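"""Detecting a genuine intersectional interaction.

Generates an otherwise purely additive cohort but injects an extra +1.0
log-odds into one stratum (12111: men, Black or Brown, no schooling, low
income, public-system users), then shows that the additive/interaction
decomposition of the fitted predicted probabilities singles that cell out.
"""

import maihda as m

codebook = m.default_codebook()
schema = m.build_schema(codebook)

cfg = m.SyntheticConfig(
    n=20_000, seed=43, sigma_int2=0.0, missingness={},
    explicit_interactions=(("12111", 1.0),),
)
cohort = m.generate_population(cfg, codebook)
filtered, _ = m.apply_complete_case_filter(cohort, codebook)
stratified, _ = m.assign_strata(filtered, schema)
result = m.run_maihda(stratified, schema, codebook, m.MaihdaOptions(ci_reps=0))

ranked = sorted(result.predictions, key=lambda p: -abs(p.interaction))[:5]
print("Top 5 strata by |interaction component| (percentage points):")
for p in ranked:
    print(
        f"  {p.stratum_id}  total {p.p_total:5.1f}%  additive {p.p_additive:5.1f}%  "
        f"interaction {p.interaction:+6.2f}  ({', '.join(p.categories)})"
    )
print(
    "\nThe injected cell 12111 tops the list: its total predicted probability "
    "exceeds what the additive main effects alone imply, which is exactly the "
    "signature the decomposition is built to expose."
)
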