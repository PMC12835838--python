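"""Design-stage sample sizes by the Cochran formula.

Prints the minimum n for a 95% confidence level, 5% margin of error and the
conservative p=0.5, with and without a finite-population correction.
"""

import maihda as m

unbounded = m.cochran_sample_size(m.SampleSizeSpec(z=1.96, epsilon=0.05, p_hat=0.5))
finite = m.cochran_sample_size(
    m.SampleSizeSpec(z=1.96, epsilon=0.05, p_hat=0.5, population=1000)
)

print(f"minimum n, unbounded population : {unbounded}")
print(f"minimum n, population of 1000   : {finite}")
print(
    "\nThe unbounded figure (385) is the usual survey planning minimum at these "
    "settings; the finite correction shrinks it when the target population is small."
)
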