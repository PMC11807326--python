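"""Reference cohort statistics used as generator defaults.

Summary statistics of a reference clinical cohort of 63 adult-type diffuse
gliomas (22 IDH-mutant, 41 IDH wild-type) drive the synthetic-cohort
generator: per-genotype, per-habitat bivariate (K^trans, ADC) intensity
distributions, habitat volume fractions, tumor volumes, demographics,
morphological feature prevalences, and the progression-free-survival hazard
structure.  Units follow the field's reporting conventions: K^trans in
10^-3 min^-1, ADC in 10^-6 mm^2/s, volumes in cm^3, times in months.
"""

from __future__ import annotations

import math

GENOTYPES = ("mutant", "wildtype")
HABITATS = (1, 2, 3)

#: Cohort sizes per IDH genotype.
GROUP_SIZES = {"mutant": 22, "wildtype": 41}

#: Across-patient mean and SD of the per-habitat mean intensities,
#: keyed genotype -> habitat -> channel statistics.
HABITAT_INTENSITY = {
    "mutant": {
        1: {"ktrans_mean": 34.27, "ktrans_sd": 18.24, "adc_mean": 1022.28, "adc_sd": 91.22},
        2: {"ktrans_mean": 33.03, "ktrans_sd": 20.48, "adc_mean": 1548.02, "adc_sd": 79.80},
        3: {"ktrans_mean": 195.01, "ktrans_sd": 27.56, "adc_mean": 1194.42, "adc_sd": 171.81},
    },
    "wildtype": {
        1: {"ktrans_mean": 57.94, "ktrans_sd": 18.08, "adc_mean": 995.98, "adc_sd": 98.94},
        2: {"ktrans_mean": 57.01, "ktrans_sd": 17.10, "adc_mean": 1584.16, "adc_sd": 116.41},
        3: {"ktrans_mean": 199.59, "ktrans_sd": 33.05, "adc_mean": 1163.91, "adc_sd": 145.55},
    },
}

#: Mean habitat volume fractions per genotype (sum to 1 within rounding).
HABITAT_FRACTIONS = {
    "mutant": (0.5254, 0.4357, 0.0389),
    "wildtype": (0.5783, 0.2811, 0.1406),
}

#: Reported SDs of the habitat volume percentages (pVol, %), used to
#: calibrate the Dirichlet concentration of the fraction sampler.
PVOL_SD_PERCENT = {
    "mutant": (21.44, 19.86, 4.77),
    "wildtype": (22.05, 18.51, 11.72),
}

#: Total-tumor (VOI) volume mean/SD per genotype, cm^3.
TUMOR_VOLUME_CM3 = {"mutant": (48.44, 37.64), "wildtype": (42.72, 23.54)}

#: Age at diagnosis, years (mean, SD).
AGE_YEARS = {"mutant": (44.9, 14.0), "wildtype": (61.2, 13.5)}

#: Male counts out of the genotype group size.
SEX_MALE_COUNTS = {"mutant": 14, "wildtype": 23}

#: WHO grade counts per genotype; wild-type adult diffuse gliomas in the
#: reference cohort are all grade-4 glioblastomas.
WHO_GRADE_COUNTS = {
    "mutant": {2: 7, 3: 7, 4: 8},
    "wildtype": {2: 0, 3: 0, 4: 41},
}

#: Tumor epicenter location counts per genotype.
LOCATION_COUNTS = {
    "mutant": {"frontal": 15, "parietal_occipital": 1, "temporal_insular": 5, "other": 1},
    "wildtype": {"frontal": 12, "parietal_occipital": 9, "temporal_insular": 12, "other": 8},
}

#: Binary morphological flag counts per genotype.
MORPHOLOGY_COUNTS = {
    "mutant": {"hemorrhage": 7, "necrosis": 9, "cysts": 14, "edema": 9},
    "wildtype": {"hemorrhage": 16, "necrosis": 30, "cysts": 22, "edema": 25},
}

#: Contrast-enhancement category counts (patchy / ringlike / no-or-mild).
ENHANCEMENT_COUNTS = {
    "mutant": {"patchy": 6, "ringlike": 7, "none_mild": 9},
    "wildtype": {"patchy": 9, "ringlike": 29, "none_mild": 3},
}

#: PFS hazard structure: exponential baseline rate per genotype (1/month),
#: log-hazard step for the high pVol-Habitat-2 subgroup, and the censoring
#: horizon (months).  The hazard ratio 2.204 is the reference wild-type
#: high-vs-low pVol-Habitat-2 estimate; baseline rates are chosen so that
#: event counts match the reference cohort (~33/41 wild-type, ~6/22 mutant)
#: under uniform dropout censoring on [0, horizon].
SURVIVAL_PARAMS = {
    "baseline_rate": {"mutant": 0.015, "wildtype": 0.07},
    "log_hr_high_pvol_h2": math.log(2.204),
    "censor_horizon_months": 50.0,
}

#: Dirichlet total concentration for the habitat-fraction sampler; gives
#: marginal SDs close to the reported pVol SDs for both genotypes.
FRACTION_CONCENTRATION = 5.0

#: Within-patient voxel SD as a fraction of the across-patient SD.
WITHIN_PATIENT_SD_RATIO = 0.5

#: Default isotropic voxel edge for generated maps, mm.
DEFAULT_VOXEL_SIZE_MM = 3.0
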