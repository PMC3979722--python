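"""Steroidogenesis product:precursor ratio panel on a simulated cohort.

Computes the per-enzyme percent product-to-precursor statistics (a
steady-state proxy for relative enzyme activity) and the total
androgens-and-precursors sum, comparing PCOS and control groups by rank-sum
test.
"""

import pandas as pd

from steroidpanel import (
    default_cohort_config,
    default_pathway_spec,
    enzyme_percent,
    generate_cohort,
    pathway_panel,
    substitute_loq_table,
)

cohort = generate_cohort(default_cohort_config(seed=11))
panel = pathway_panel(cohort)

pd.set_option("display.width", 140)
cols = ["statistic", "pcos_median", "pcos_p2_5", "pcos_p97_5",
        "control_median", "control_p2_5", "control_p97_5", "p_value"]
print(panel[cols].round(2).to_string(index=False))

# worked single-subject check on the published group medians:
medians = pd.DataFrame([{
    "testosterone": 49.2, "androstenedione": 202.9, "17oh_progesterone": 79.6,
    "17oh_pregnenolone": 477.8, "pregnenolone": 35.0, "dhea": 502.5,
    "progesterone": 12.0, "deoxycorticosterone": 16.0, "corticosterone": 151.2,
    "11_deoxycortisol": 15.0, "cortisol": 11300.0, "cortisone": 2030.0,
    "18oh_corticosterone": 39.9,
}])
pct = enzyme_percent(substitute_loq_table(medians), "17b_hsd",
                     default_pathway_spec())
print(f"\n17b-HSD on the published PCOS medians: {pct.iloc[0]:.1f}% "
      "(testosterone / androstenedione x 100)")
print(
    "\nRatios are concentration proxies, not kinetic measurements; the"
    "\n11b-hydroxylase row is ~10^4 % because cortisol (ug/dL scale) dwarfs"
    "\nits ng/dL-scale precursors."
)
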