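"""Generate a synthetic storage cohort and inspect its fatty-acid trend.

Builds the default design — 8 monthly rounds of 20 rice samples — and
prints the per-month mean fatty acid value. The upward trend is the
storage-aging signal every downstream model tries to recover.
"""

import pandas as pd

import ricefusion as rf

cohort = rf.generate_cohort(rf.CohortConfig(seed=0))
frame = pd.DataFrame(
    {"month": [s.month for s in cohort], "fatty_acid": [s.fatty_acid for s in cohort]}
)
print(f"{len(cohort)} samples over {frame['month'].nunique()} months")
print(frame.groupby("month")["fatty_acid"].agg(["mean", "std"]).round(2))
print(
    "\nFatty acid (mg/100 g) rises roughly linearly with storage month;"
    "\nthe spread within a month is sample-to-sample biological noise."
)
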