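"""The complete two-model MAIHDA workflow on a synthetic cohort.

Fits the null (stratum random intercept only) and full (plus additive main
effects) logistic models, then prints the variance partition coefficients,
the proportional change in variance, discriminatory accuracy, the fixed-effect
odds ratios, and the most and least likely intersectional strata.
"""

import maihda as m

codebook = m.default_codebook()
schema = m.build_schema(codebook)

cohort = m.generate_population(m.SyntheticConfig(n=2652, seed=1), codebook)
filtered, _ = m.apply_complete_case_filter(cohort, codebook)
stratified, strata = m.assign_strata(filtered, schema)

result = m.run_maihda(stratified, schema, codebook, m.MaihdaOptions(seed=1))

s = result.summary()
print(f"observed strata          : {s['n_observed_strata']} of {s['n_possible_strata']}")
print(f"VPC null / full model    : {s['vpc_null']:.1f}% / {s['vpc_full']:.1f}%")
print(f"PCV                      : {s['pcv']:.1f}%  (complement {s['interaction_share']:.1f}% = residual interaction)")
print(f"AUC null / full model    : {s['auc_null']:.2f} / {s['auc_full']:.2f}")

print("\nFixed-effect odds ratios (full model):")
print(result.coefficients_table().round(2).to_string(index=False))

low, high = m.extremes(result.predictions, k=5)
print("\nFive strata with the lowest null-model predicted probability (%):")
print(low.round(2).to_string(index=False))
print("\nFive strata with the highest:")
print(high.round(2).to_string(index=False))
print(
    "\nA large VPC drop with PCV near 100% says the between-stratum inequality "
    "is almost entirely additive in the five dimensions; the stratum tables "
    "show which intersectional profiles sit at the extremes."
)
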