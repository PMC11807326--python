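# Methods

This note documents the models, defaults, and design choices behind
`gliohab`, and what the synthetic test bed does and does not establish.

## Parametric map reconstruction

ADC is the closed-form two-point estimate `ln(S_0/S_b)/b` from b = 0 and
b = 1000 s/mm² signals, reported in 10⁻⁶ mm²/s. Voxels with non-positive
signal are flagged invalid; negative estimates (signal increase under
diffusion weighting, physically meaningless) are clamped to zero and
flagged rather than propagated.

K^trans comes from the standard Tofts model, which treats tissue as a
single extravascular extracellular compartment of volume fraction `v_e`
exchanging contrast agent with plasma at rate constant `K^trans` (min⁻¹),
with washout `k_ep = K^trans/v_e`. Inputs are tissue *concentration*
curves; converting MR signal to concentration (T1 mapping, relaxivity) is
upstream of this package, as are plasma-volume terms (extended Tofts) and
motion correction. The forward model is a trapezoidal convolution on the
acquisition grid — 30 uniform phases over 4.7 min by default, matching a
standard DCE protocol — and the arterial input function defaults to the
classic biexponential population curve
`C_p(t) = D (3.99 e^{−0.144 t} + 4.78 e^{−0.0111 t})` for a 0.1 mmol/kg
dose; any tabulated AIF can be supplied instead.

Inversion is bounded nonlinear least squares over
`K^trans ∈ [0, 5] min⁻¹`, `v_e ∈ (0.001, 1]`. The residual landscape has a
flat ridge at large `k_ep` (fast-equilibrium curves are nearly
`v_e`-insensitive), so the optimizer is multistarted from the best
*diverse* points of a log-spaced coarse grid; a full coarse-grid fallback
handles non-convergence, and an all-zero curve returns `K^trans = 0` with
`v_e` flagged non-identifiable. On noiseless forward-simulated curves the
inversion recovers parameters to well under 1% across a 10×10 sweep of
the bounds (tested). Vendor DCE pipelines leave their model variant and
AIF unreported, so numerical equality with vendor maps is not claimed —
this module is a transparent, testable stand-in.

## Cohort habitat model

"Cohort-based" clustering means one k-means fit on voxels pooled across
all patients, then per-patient nearest-centroid segmentation: habitat
definitions are shared, so habitat features are comparable across
patients. Channels are z-scored on the pooled voxels before clustering;
K^trans (~10–200 ×10⁻³ min⁻¹) and ADC (~900–1700 ×10⁻⁶ mm²/s) differ by
an order of magnitude in scale, and unscaled Euclidean k-means would be
ADC-dominated, contradicting the K^trans-driven definition of Habitat 3.
Raw-unit clustering and per-patient voxel caps (uniform subsampling under
the cohort seed) remain config-exposed because practice varies.

k-means uses k-means++ initialization, 10 restarts, 300 max iterations,
relative tolerance 1e-4, and a fixed seed (scikit-learn's Lloyd
implementation, which also repairs empty clusters internally). k = 3 is
the analysis default; other k are accepted but carry no habitat
semantics. Labeling is a deterministic rule on original-unit centroids:
highest K^trans → Habitat 3; of the remaining two, lower ADC → Habitat 1,
higher → Habitat 2. A K^trans tie for the maximum is broken toward higher
ADC and logged. Assignment ties go to the lowest cluster index; non-finite
voxels stay unlabeled and are logged.

## Features

Per habitat: mean ADC, mean K^trans, volume = voxel count × voxel volume
(cm³), and pVol = 100 × count/mask count. By construction volumes sum to
the VOI volume and pVols to 100 exactly — enforced as an invariant, not a
tolerance. An empty habitat has volume 0, pVol 0, and *undefined* means,
encoded as missing and excluded listwise from group summaries and from
the patients entering models that use that feature; both are logged.
Volumes are reported in cm³ throughout (tumor volumes of tens of cm³ at
~27 mm³ voxels; the mm³ scale would be three orders larger).

## IDH prediction statistics

Group comparisons gate on Shapiro-Wilk normality per group at α = 0.05:
Welch's t if both pass, Mann-Whitney U otherwise, two-tailed.

AUC is the Mann-Whitney pair-counting estimator with half-credit ties;
its variance and the two-model comparison use DeLong placement values,
with normal-approximation CIs clipped to [0, 1]. The positive class for
feature ROCs is IDH wild-type (wild-type tumors have higher K^trans, so
published feature AUCs exceed 0.5 under this orientation); orientation is
auto-detected and recorded. Operating points maximize Youden's J, ties
broken toward higher specificity. Degenerate comparisons (identical score
vectors) report difference 0, p = 1, flagged.

Model building per candidate block (clinical/morphological covariates
plus the tumor-VOI or habitat feature set): univariable logistic screen
at p < 0.05, iterative removal of variables with VIF ≥ 5
(`VIF_j = 1/(1−R²_j)` with intercept), then *backward elimination* on
Wald p at 0.05. "Stepwise" is ambiguous in clinical reporting; backward
elimination is the implemented reading, the threshold is configurable,
and the elimination path is returned so any discrepancy is auditable.
Logistic fits are maximum likelihood (statsmodels); separation is
detected via diverging coefficients and flagged. Hosmer-Lemeshow uses
deciles of risk, χ² = Σ(O−E)²/(E(1−E/n)), df = g−2 (the fitted-model
convention; with externally specified true probabilities the statistic is
~χ²_g, which the tests verify). Degenerate bins are merged and logged.

LOOCV fixes the variable set selected on the full data and refits
coefficients per fold — validating the chosen model's coefficients, not
re-running selection, which is the common clinical-reporting reading;
per-fold re-selection is available but off by default. Single-class
training folds fall back to the full-data fit and are flagged.

## Survival

Within each genotype, patients split at the feature median (median value
to the low subgroup, matching a strict high-side cut). Kaplan-Meier
medians are the earliest time the curve reaches 0.5; subgroups are
compared by log-rank and by a two-group Cox model with Efron tie handling
(PFS times have monthly-scale resolution, so ties are expected; Breslow
is configurable). Monotone partial likelihood falls back to a lightly
ridge-penalized fit, flagged. Patients without progression are censored
at last follow-up as given in the cohort table.

## Synthetic cohort generator

The generator reproduces the *statistical* structure of the reference
63-patient cohort; each default is the published group-level value where
one exists:

| parameter | default | source/rationale |
|---|---|---|
| group sizes | 22 mutant / 41 wild-type | reference cohort |
| habitat intensity means/SDs | per genotype × habitat table | reference cohort (across-patient) |
| habitat mean fractions | (0.525, 0.436, 0.039) mut; (0.578, 0.281, 0.141) wt | reference pVol means |
| fraction distribution | Dirichlet, total concentration 5.0 | sum-to-one by construction; marginal SDs ≈ reference pVol SDs |
| within-patient voxel SD | 0.5 × across-patient SD | unreported; keeps habitats separable, consistent with a successful 3-cluster solution |
| tumor volume | lognormal moment-matched to mean/SD (cm³) | positivity with the reported moments |
| voxel size | 3 mm isotropic | typical post-registration map resolution; ~1700 tumor voxels/patient |
| PFS | exponential; baseline 0.07 (wt) / 0.015 (mut) per month; log-HR ln(2.204) on high pVol-Habitat-2; uniform dropout on (0, 50] months | HR is the published wild-type estimate; baselines chosen so event counts (~33/41 wt, ~6/22 mut) and ~20% wild-type censoring match the reference follow-up pattern |

Spatial layout is a modeling choice: Habitat 2 occupies the tumor core,
Habitat 3 the outer rim, Habitat 1 the shell between, ordered by the
normalized ellipsoidal radius — mimicking the observed geography of
hypoxic tissue around central necrosis and leaky vasculature toward the
periphery. Masks are mildly anisotropic ellipsoids; habitat voxel counts
use largest-remainder apportionment, so an extreme fraction draw can
leave a habitat empty (recorded as volume 0, not an error). Patient-level
habitat means are Gaussian draws left unclamped so configured moments are
preserved exactly; a low-mean habitat can therefore occasionally produce
small negative K^trans values — acceptable for a statistical emulator,
noted as unphysical. Randomness is one seed sequence per cohort with one
spawned sub-stream per patient plus a survival stream, so regenerating
any patient is reproducible and cohorts are bit-identical under a fixed
seed.

What the generator does **not** emulate: MR signal formation (noise,
bias fields, partial volume), spatial autocorrelation of voxel noise,
irregular tumor shapes, correlations between clinical covariates and
imaging beyond genotype, and lesion dynamics. Passing tests on this bed
therefore demonstrate correctness of the *analysis machinery* and
recoverability of planted effects — not clinical performance on real
gliomas, where habitat separability is lower and the published
cross-validated AUCs cannot be independently reproduced without the
private data.

## Problem sizes and numerical choices

Default test and acceptance runs use the full 63-patient structure at
3 mm voxels (~10⁵ pooled voxels), 1000 replicates for simulated-AUC
estimates, and 500 replicate cohorts for Cox recovery; unit tests use a
reduced 24-patient cohort at 6 mm voxels, sizes chosen to keep the suites
quick while leaving Monte-Carlo error well inside the asserted
tolerances. Wald CIs use z = 1.96; all tests are two-tailed at α = 0.05.
Affine agreement for NIfTI input is required to 1e-4 (no resampling is
performed; inputs must be pre-aligned upstream).

## Known limitations

* The Tofts module assumes concentration inputs and a population AIF;
  absolute K^trans values are AIF-dependent.
* Backward elimination and LOOCV-without-reselection are single readings
  of ambiguous clinical-statistics phrasing (alternatives are
  config-exposed).
* The multivariable Cox analysis is limited to the subgroup indicator;
  continuous-covariate Cox models are out of scope.
* Habitat semantics are defined only for k = 3.
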