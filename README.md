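# gliohab

Habitat imaging analysis of adult-type diffuse gliomas from multiparametric
MRI. `gliohab` is a Python library (plus a thin CLI) for researchers who
study intratumor heterogeneity with quantitative imaging: it clusters tumor
voxels from DCE-MRI and DWI parametric maps into spatial *habitats*, turns
them into per-patient features, predicts IDH genotype with screened logistic
models, and relates habitat burden to progression-free survival (PFS).

## What it computes

**Parametric maps.** ADC from a two-b-value DWI pair,
`ADC = ln(S_0/S_b)/b` (reported in 10⁻⁶ mm²/s), and K^trans from DCE
concentration-time curves via the standard Tofts model

```
C_t(t) = K^trans ∫₀ᵗ C_p(τ) e^{−k_ep (t−τ)} dτ,   k_ep = K^trans / v_e,
```

inverted by bounded nonlinear least squares against a biexponential
population arterial input function.

**Habitats.** One k-means model (k = 3) is fitted on z-scored
(K^trans, ADC) voxels pooled across the whole cohort, so habitat
definitions are shared between patients. Centroids define the semantics:
the highest-K^trans cluster is Habitat 3 (hyper-vasopermeability); of the
rest, the low-ADC cluster is Habitat 1 (hypo-vasopermeability,
hyper-cellularity) and the high-ADC cluster Habitat 2
(hypo-vasopermeability, hypo-cellularity). Each tumor voxel is assigned to
its nearest centroid, and per patient the package extracts ADC_Mean,
K^trans_Mean, Volume (cm³) and pVol (%) per habitat plus tumor-VOI values.

**Statistics.** Shapiro-gated Welch-t / Mann-Whitney group comparisons;
Mann-Whitney pair-counting AUC with DeLong variance and the paired DeLong
test; univariable screening at p < 0.05 and VIF < 5 followed by backward
stepwise logistic regression; Hosmer-Lemeshow calibration; leave-one-out
cross-validation. Survival: within-genotype median splits, Kaplan-Meier
with log-rank, and Cox proportional-hazards hazard ratios (Efron ties).

**Synthetic cohorts.** Because the motivating clinical dataset is private,
the package ships a generator whose defaults reproduce the reference
cohort's statistical structure (group sizes 22/41, per-genotype habitat
intensity means/SDs, habitat volume fractions, demographics, and a planted
pVol-Habitat-2 PFS hazard ratio of 2.204), giving every downstream stage a
ground-truthed test bed.

## Worked example

```python
from gliohab import (CohortConfig, generate_cohort, build_voxel_table,
                     kmeans_fit, assign_habitat_labels, segment_case)

cohort = generate_cohort(CohortConfig(seed=1))       # 63 synthetic patients
table  = build_voxel_table(cohort.cases, seed=1)     # pooled tumor voxels
model  = assign_habitat_labels(kmeans_fit(table, k=3, seed=1))
labels = segment_case(cohort.cases[0], model)
```

Running `python examples/03_habitat_clustering.py` prints:

```
pooled 103665 tumor voxels from 63 patients
habitat centroids (original units):
  Habitat 1: K^trans   52.2 x1e-3/min, ADC   978.1 x1e-6 mm^2/s
  Habitat 2: K^trans   45.4 x1e-3/min, ADC  1544.4 x1e-6 mm^2/s
  Habitat 3: K^trans  193.6 x1e-3/min, ADC  1164.8 x1e-6 mm^2/s
voxel habitat accuracy vs ground truth: 0.9981
```

The centroids land where the habitat definitions put them — two
low-permeability clusters separated by diffusivity and one
high-permeability cluster — and the cohort segmentation recovers 99.8% of
the generator's true voxel labels. `examples/05_pfs_survival.py` continues
with the prognosis end: median-splitting wild-type patients on
pVol-Habitat-2 gives subgroup median PFS of 16.4 vs 5.7 months and a Cox
HR of 4.41 (95% CI 1.80–10.82) in that particular 41-patient replicate —
one draw around the planted HR of 2.204, illustrating how wide
single-cohort hazard estimates are.

The other examples cover map reconstruction (`02`), generator fidelity
(`01`), and IDH model building with LOOCV (`04`).

## Command line

The same stages are runnable from a shell:

```
gliohab run-all --out myrun --seed 7          # simulate → cluster → … → report
gliohab simulate --out myrun                  # individual stages
gliohab reconstruct-adc --b0 b0.nii.gz --b1000 dwi.nii.gz --out adc.nii.gz
```

`run-all` writes cohort/feature/model/survival CSVs, habitat label NIfTIs,
and a manifest (config hash, seed, package versions) that suffices to
reproduce the run. With `enhanced_subgroup` on (default), the analysis is
repeated after excluding no/mild-enhancement patients.

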