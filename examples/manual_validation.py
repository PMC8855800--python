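"""Automated-vs-manual validation: recover a known measurement bias.

Simulates paired automated/manual annular measurements in which the automated
pipeline reads 2.3% large, then checks that the percentage-difference summary
recovers the bias and that no covariate shows a systematic relationship.
"""

import pandas as pd

from cinemorph import compare_to_manual, generate_cohort

_, pairs = generate_cohort(
    100, manual_bias=0.023, manual_noise_sd=0.01, seed=11
)
cov = pairs[["age", "bsa", "sex", "plane_deviation"]]
report = compare_to_manual(pairs["auto_mm"], pairs["manual_mm"], cov)

print(f"pairs: {report.n_pairs}")
print(f"mean difference:   {report.mean_diff_mm:+.3f} mm")
print(f"mean % difference: {100 * report.mean_pct_diff:+.2f} %")
print("\ncovariate slopes for the % difference (should all be null):")
with pd.option_context("display.float_format", "{:.4g}".format):
    print(report.coefficients)
# The mean % difference reproduces the injected 2.3% bias; slopes within
# ~2 SE of zero mean the error carries no age/size/sex/acquisition structure.
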