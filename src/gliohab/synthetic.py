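"""Synthetic glioma cohort generator with ground-truth habitats.

Each synthetic patient is an ellipsoidal tumor mask on a 3-D voxel grid,
partitioned spatially into three habitats — Habitat 2 at the core,
Habitat 3 as the outer rim, Habitat 1 in between — with volume fractions
drawn from a Dirichlet distribution centered on the genotype's reference
fractions.  Habitat intensities follow a two-level normal model: a
patient-level (K^trans, ADC) mean per habitat drawn from the
across-patient distribution, then voxel values around it with a
within-patient SD (default half the across-patient SD).  Clinical
covariates, morphology flags, and exponential progression-free survival
with a high-vs-low pVol-Habitat-2 hazard step complete the cohort.

The generator reproduces the *statistical* structure the analysis
assumes (group-level means, SDs, fractions, hazards); it does not
simulate MR signal formation, noise fields, or lesion growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import defaults as d
from .habitats import ParametricCase

GENOTYPES = d.GENOTYPES
HABITATS = d.HABITATS


def _probs(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults reproduce the reference 63-patient cohort (22 IDH-mutant,
    41 wild-type): per-genotype, per-habitat intensity means/SDs, mean
    habitat volume fractions, tumor volume and age distributions,
    morphology prevalences, and the PFS hazard structure.
    """

    n_mutant: int = d.GROUP_SIZES["mutant"]
    n_wildtype: int = d.GROUP_SIZES["wildtype"]
    habitat_intensity: dict = field(default_factory=lambda: {
        g: {h: dict(d.HABITAT_INTENSITY[g][h]) for h in HABITATS} for g in GENOTYPES})
    habitat_fractions: dict = field(default_factory=lambda: {
        g: tuple(d.HABITAT_FRACTIONS[g]) for g in GENOTYPES})
    fraction_concentration: float = d.FRACTION_CONCENTRATION
    within_sd_ratio: float = d.WITHIN_PATIENT_SD_RATIO
    tumor_volume: dict = field(default_factory=lambda: {
        g: tuple(d.TUMOR_VOLUME_CM3[g]) for g in GENOTYPES})  # cm^3 (mean, sd)
    voxel_size_mm: float = d.DEFAULT_VOXEL_SIZE_MM
    age: dict = field(default_factory=lambda: {g: tuple(d.AGE_YEARS[g]) for g in GENOTYPES})
    sex_male_p: dict = field(default_factory=lambda: {
        g: d.SEX_MALE_COUNTS[g] / d.GROUP_SIZES[g] for g in GENOTYPES})
    who_grade_probs: dict = field(default_factory=lambda: {
        g: _probs(d.WHO_GRADE_COUNTS[g]) for g in GENOTYPES})
    location_probs: dict = field(default_factory=lambda: {
        g: _probs(d.LOCATION_COUNTS[g]) for g in GENOTYPES})
    morphology_probs: dict = field(default_factory=lambda: {
        g: {k: v / d.GROUP_SIZES[g] for k, v in d.MORPHOLOGY_COUNTS[g].items()}
        for g in GENOTYPES})
    enhancement_probs: dict = field(default_factory=lambda: {
        g: _probs(d.ENHANCEMENT_COUNTS[g]) for g in GENOTYPES})
    survival: dict = field(default_factory=lambda: {
        "baseline_rate": dict(d.SURVIVAL_PARAMS["baseline_rate"]),
        "log_hr_high_pvol_h2": d.SURVIVAL_PARAMS["log_hr_high_pvol_h2"],
        "censor_horizon_months": d.SURVIVAL_PARAMS["censor_horizon_months"],
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutant < 2 or self.n_wildtype < 2:
            raise ValueError("group sizes must be >= 2")
        for g in GENOTYPES:
            fr = np.asarray(self.habitat_fractions[g], dtype=float)
            if (fr < 0).any() or not math.isclose(fr.sum(), 1.0, abs_tol=1e-6):
                raise ValueError(f"{g}: habitat fractions must be >= 0 and sum to 1")
            for h in HABITATS:
                p = self.habitat_intensity[g][h]
                if p["ktrans_sd"] <= 0 or p["adc_sd"] <= 0:
                    raise ValueError(f"{g}/habitat {h}: SDs must be positive")
            if self.tumor_volume[g][0] <= 0 or self.tumor_volume[g][1] <= 0:
                raise ValueError(f"{g}: tumor volume mean/SD must be positive")
        for g, rate in self.survival["baseline_rate"].items():
            if rate <= 0:
                raise ValueError(f"{g}: baseline hazard must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("who_grade_probs",):
            if key in raw:
                raw[key] = {g: {int(k): v for k, v in m.items()} for g, m in raw[key].items()}
        for key in ("habitat_intensity",):
            if key in raw:
                raw[key] = {g: {int(h): v for h, v in m.items()} for g, m in raw[key].items()}
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class CaseTruth:
    """Ground truth for one synthetic case."""

    labels: np.ndarray  # habitat label grid, 0 outside mask
    habitat_means: dict[int, dict[str, float]]  # patient-level true means
    fractions: tuple[float, float, float]  # realized voxel fractions
    counts: tuple[int, int, int]


@dataclass
class SyntheticCohort:
    cases: list[ParametricCase]
    cohort_table: pd.DataFrame
    truth: dict[str, CaseTruth]


# ---------------------------------------------------------------------------

def _ellipsoid_mask(volume_cm3: float, voxel_mm: float, rng: np.random.Generator):
    """Axis-aligned ellipsoid mask of approximately the target volume,
    with mildly anisotropic semi-axes; returns (mask, radius_grid) where
    radius is the normalized ellipsoidal coordinate."""
    vol_mm3 = max(volume_cm3, 1e-3) * 1000.0
    aniso = rng.uniform(0.75, 1.3, size=3)
    r0 = (3.0 * vol_mm3 / (4.0 * np.pi * np.prod(aniso))) ** (1.0 / 3.0)
    axes = r0 * aniso  # mm
    half = np.ceil(axes / voxel_mm).astype(int) + 1
    shape = 2 * half + 1
    coords = [
        (np.arange(s) - h) * voxel_mm / a
        for s, h, a in zip(shape, half, axes)
    ]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    radius = np.sqrt(gx**2 + gy**2 + gz**2)
    mask = radius <= 1.0
    if not mask.any():
        mask[tuple(half)] = True  # sub-voxel tumor: keep the center voxel
    return mask, radius


def _habitat_counts(n_mask: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of mask voxels to the 3 habitats."""
    raw = fractions * n_mask
    counts = np.floor(raw).astype(int)
    for _ in range(n_mask - counts.sum()):
        counts[np.argmax(raw - counts)] += 1
    return counts


def _layout_labels(mask: np.ndarray, radius: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Spatial layout: Habitat 2 at the core, Habitat 3 as the rim,
    Habitat 1 in between, ordered by the normalized ellipsoid radius."""
    labels = np.zeros(mask.shape, dtype=np.int16)
    idx = np.flatnonzero(mask.ravel())
    order = idx[np.argsort(radius.ravel()[idx], kind="stable")]
    n1, n2, n3 = counts
    flat = labels.ravel()
    flat[order[:n2]] = 2
    flat[order[n2:n2 + n1]] = 1
    flat[order[n2 + n1:]] = 3
    return flat.reshape(mask.shape)


def _lognormal_volume(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Lognormal draw moment-matched to the given mean/SD (keeps volumes
    positive)."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _categorical(rng: np.random.Generator, probs: dict) -> object:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.asarray([probs[k] for k in keys], float))]


def generate_case(
    patient_id: str,
    genotype: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[ParametricCase, CaseTruth]:
    """Generate one patient's parametric maps, mask, and ground truth."""
    volume = _lognormal_volume(*config.tumor_volume[genotype], rng)
    mask, radius = _ellipsoid_mask(volume, config.voxel_size_mm, rng)
    n_mask = int(mask.sum())
    base = np.asarray(config.habitat_fractions[genotype], dtype=float)
    alpha = config.fraction_concentration * np.clip(base, 1e-6, None)
    fractions = rng.dirichlet(alpha)
    counts = _habitat_counts(n_mask, fractions)
    labels = _layout_labels(mask, radius, counts)

    ktrans = np.zeros(mask.shape)
    adc = np.zeros(mask.shape)
    habitat_means: dict[int, dict[str, float]] = {}
    for h in HABITATS:
        p = config.habitat_intensity[genotype][h]
        mu_kt = rng.normal(p["ktrans_mean"], p["ktrans_sd"])
        mu_adc = rng.normal(p["adc_mean"], p["adc_sd"])
        habitat_means[h] = {"ktrans": float(mu_kt), "adc": float(mu_adc)}
        sel = labels == h
        n_h = int(sel.sum())
        if n_h:
            ktrans[sel] = rng.normal(mu_kt, config.within_sd_ratio * p["ktrans_sd"], n_h)
            adc[sel] = rng.normal(mu_adc, config.within_sd_ratio * p["adc_sd"], n_h)
    case = ParametricCase(
        patient_id=patient_id,
        ktrans_map=ktrans,
        adc_map=adc,
        mask=mask,
        voxel_volume=config.voxel_size_mm**3,
    )
    truth = CaseTruth(
        labels=labels,
        habitat_means=habitat_means,
        fractions=tuple(counts / n_mask),
        counts=tuple(int(c) for c in counts),
    )
    return case, truth


def generate_clinical_row(
    patient_id: str, genotype: str, config: CohortConfig, rng: np.random.Generator
) -> dict:
    mean_age, sd_age = config.age[genotype]
    morph = config.morphology_probs[genotype]
    return {
        "patient_id": patient_id,
        "genotype": genotype,
        "idh_mutant": int(genotype == "mutant"),
        "age": float(np.round(np.clip(rng.normal(mean_age, sd_age), 18, 95), 1)),
        "sex": "M" if rng.random() < config.sex_male_p[genotype] else "F",
        "who_grade": int(_categorical(rng, config.who_grade_probs[genotype])),
        "location": _categorical(rng, config.location_probs[genotype]),
        "hemorrhage": int(rng.random() < morph["hemorrhage"]),
        "necrosis": int(rng.random() < morph["necrosis"]),
        "cysts": int(rng.random() < morph["cysts"]),
        "edema": int(rng.random() < morph["edema"]),
        "enhancement": _categorical(rng, config.enhancement_probs[genotype]),
    }


def generate_survival(
    pvol_h2,
    genotypes,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential PFS with a hazard step on high pVol-Habitat-2.

    The rate is the genotype baseline times exp(coef) for patients whose
    pVol-Habitat-2 exceeds the within-genotype median.  Censoring is
    uniform dropout on (0, horizon]; the event flag marks progression
    observed before dropout.  Times are rounded to 0.1 months.

    ``pvol_h2`` may be an array of values or a list of
    ``HabitatFeatureRecord`` (their Habitat-2 pVol is used).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if isinstance(pvol_h2, (list, tuple)) and len(pvol_h2) and hasattr(pvol_h2[0], "pvol"):
        pvol = np.asarray([r.pvol[2] for r in pvol_h2], dtype=float)
    else:
        pvol = np.asarray(pvol_h2, dtype=float)
    genotypes = np.asarray(genotypes)
    horizon = float(config.survival["censor_horizon_months"])
    coef = float(config.survival["log_hr_high_pvol_h2"])
    rates = np.empty(pvol.size)
    high = np.zeros(pvol.size, dtype=int)
    for g in np.unique(genotypes):
        sel = genotypes == g
        med = np.median(pvol[sel])
        high[sel] = (pvol[sel] > med).astype(int)
        rates[sel] = config.survival["baseline_rate"][str(g)] * np.exp(coef * high[sel])
    t_event = rng.exponential(1.0 / rates)
    t_censor = rng.uniform(0.0, horizon, size=pvol.size)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    time = np.maximum(np.round(time, 1), 0.1)
    return pd.DataFrame(
        {"pfs_months": time, "progression": event, "high_pvol_h2": high}
    )


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort, deterministically from the seed.

    One RNG sub-stream per patient (spawned from the cohort seed) plus a
    dedicated survival stream, so partial regeneration is reproducible.
    """
    config = config or CohortConfig()
    n = config.n_mutant + config.n_wildtype
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(n + 1)
    genotypes = ["mutant"] * config.n_mutant + ["wildtype"] * config.n_wildtype
    cases, truth, rows = [], {}, []
    for i, genotype in enumerate(genotypes):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(streams[i])
        case, tr = generate_case(pid, genotype, config, rng)
        rows.append(generate_clinical_row(pid, genotype, config, rng))
        cases.append(case)
        truth[pid] = tr
    table = pd.DataFrame(rows)
    surv = generate_survival(
        [100.0 * truth[pid].fractions[1] for pid in table["patient_id"]],
        table["genotype"].to_numpy(),
        config,
        np.random.default_rng(streams[n]),
    )
    table = pd.concat([table, surv[["pfs_months", "progression"]]], axis=1)
    return SyntheticCohort(cases=cases, cohort_table=table, truth=truth)


def simulate_two_group_pfs(
    n_low: int,
    n_high: int,
    baseline_rate: float,
    hazard_ratio: float,
    censor_max_months: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two fixed subgroups with exponential PFS at a known hazard ratio
    and uniform dropout censoring — the parameter-recovery workhorse for
    Cox estimation checks."""
    if baseline_rate <= 0 or hazard_ratio <= 0:
        raise ValueError("rates must be positive")
    ind = np.concatenate([np.zeros(n_low, dtype=int), np.ones(n_high, dtype=int)])
    rates = baseline_rate * hazard_ratio**ind
    t_event = rng.exponential(1.0 / rates)
    t_censor = rng.uniform(0.0, censor_max_months, size=ind.size)
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, t_censor),
            "event": (t_event <= t_censor).astype(int),
            "high": ind,
        }
    )
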