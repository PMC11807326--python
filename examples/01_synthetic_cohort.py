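"""Generate a synthetic glioma cohort and check it against its own config.

Builds the default 63-patient cohort (22 IDH-mutant, 41 wild-type) and
compares the realized across-patient Habitat-1 K^trans means and
Habitat-2 volume fractions with the configured generative parameters.
"""

import numpy as np

from gliohab import CohortConfig, generate_cohort

config = CohortConfig(seed=42)
cohort = generate_cohort(config)

print(f"cohort: {len(cohort.cases)} patients "
      f"({(cohort.cohort_table.genotype == 'mutant').sum()} mutant, "
      f"{(cohort.cohort_table.genotype == 'wildtype').sum()} wild-type)")

for genotype in ("mutant", "wildtype"):
    pids = cohort.cohort_table.query("genotype == @genotype")["patient_id"]
    kt1 = np.mean([cohort.truth[p].habitat_means[1]["ktrans"] for p in pids])
    fr2 = np.mean([cohort.truth[p].fractions[1] for p in pids])
    cfg_kt = config.habitat_intensity[genotype][1]["ktrans_mean"]
    cfg_fr = config.habitat_fractions[genotype][1]
    print(f"{genotype:>9}: true Habitat-1 K^trans mean {kt1:6.2f} (configured {cfg_kt}), "
          f"Habitat-2 fraction {fr2:.3f} (configured {cfg_fr})")

events = cohort.cohort_table.groupby("genotype")["progression"].sum()
print(f"PFS events: {events.to_dict()}  "
      "(wild-type progresses far more often, as configured)")
# Realized values fluctuate around the configured parameters with
# sampling error ~SD/sqrt(n); exact agreement is not expected.
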