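"""Prognostic value of Habitat-2 volume fraction for PFS.

Median-splits wild-type patients on pVol-Habitat-2, compares the
subgroups with Kaplan-Meier/log-rank, and estimates the high-vs-low
hazard ratio with a Cox model.
"""

import numpy as np

from gliohab import (
    CohortConfig, cohort_feature_table, cox_fit, extract_features,
    generate_cohort, kaplan_meier, median_split,
)

cohort = generate_cohort(CohortConfig(seed=9))
recs = [extract_features(c, cohort.truth[c.patient_id].labels) for c in cohort.cases]
joined = cohort_feature_table(recs, cohort.cohort_table)

wt = joined[joined["genotype"] == "wildtype"]
labels, threshold = median_split(wt["pvol_h2"].to_numpy())
print(f"wild-type median pVol-Habitat-2: {threshold:.1f}% "
      f"({(labels == 'high').sum()} high, {(labels == 'low').sum()} low)")

km = kaplan_meier(wt["pfs_months"], wt["progression"], labels)
for name, curve in km.curves.items():
    med = "not reached" if np.isnan(curve.median) else f"{curve.median:.1f} mo"
    print(f"  {name:>4}: n={curve.n}, events={curve.events}, median PFS {med}")
print(f"log-rank p = {km.logrank_p:.3f}")

cox = cox_fit(wt["pfs_months"], wt["progression"], (labels == "high").astype(int))
print(f"Cox HR (high vs low) = {cox.hr:.2f} "
      f"(95% CI {cox.ci[0]:.2f}-{cox.ci[1]:.2f}, p = {cox.p:.3f})")
# HR > 1 means patients with a larger Habitat-2 share progress faster;
# the generator plants this effect (true HR 2.204), and a single
# 41-patient cohort estimates it with wide uncertainty.
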