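"""Compare the free-NAD(P)H fraction a1 between two culture conditions.

Builds a per-cell metric table at the literature scale of effect — a1 of
77% for cells without collagen versus 83% for cells in fibroblast-
structured collagen, 3-point between-cell spread, 40 cells per group —
and runs the full comparison procedure: percentile trimming, Shapiro-Wilk
normality, Welch's t-test.
"""

import numpy as np
import pandas as pd

from flimcell import GroupTable, summarize_groups

rng = np.random.default_rng(4)
rows = [
    {"group": group, "cell_label": f"{group}:{i}", "compartment": "cytoplasm",
     "metric": "a1", "value": v}
    for group, mean in [("no_collagen", 77.0), ("collagen_fibroblasts", 83.0)]
    for i, v in enumerate(rng.normal(mean, 3.0, size=40))
]
table = GroupTable(pd.DataFrame(rows))

summary, pairwise = summarize_groups(table, metric="a1", compartment="cytoplasm")
print(summary[["group", "n", "n_trimmed", "mean", "sd", "shapiro_p"]].to_string(index=False))
print()
print(pairwise[["group_a", "group_b", "t", "df", "p", "significant"]].to_string(index=False))
# A significant difference in a1 at this effect size indicates the two
# conditions sit at distinct metabolic states (more free NAD(P)H = more
# glycolytic).
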