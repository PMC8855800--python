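"""Cohort outlier QC: z-score exclusion on a synthetic measurement cohort.

Draws 1000 subjects with 5% gross outliers injected, applies |z| > 3
exclusion, and exports the surviving phenotypes as a tab-delimited table.
"""

import tempfile
from pathlib import Path

from cinemorph import apply_qc, export_phenotypes, generate_cohort

records, _ = generate_cohort(1000, outlier_fraction=0.05, seed=42)
apply_qc(records, k=3.0)

excluded = [r for r in records if r.excluded]
print(f"{len(excluded)} of {len(records)} subjects excluded at |z| > 3")
print("example reasons:", sorted({r.exclusion_reason for r in excluded})[:3])

out = Path(tempfile.mkdtemp()) / "phenotypes.tsv"
df = export_phenotypes(records, out)
print(f"exported {len(df)} subjects -> {out}")
# ~5% of subjects carry injected 6-SD outliers; nearly all are caught, while
# a clean normal cohort would lose only ~0.27% at the same threshold.
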