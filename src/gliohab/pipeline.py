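"""End-to-end habitat analysis pipeline.

Stages: simulate (or load) a cohort of co-registered K^trans/ADC cases
-> cohort k-means habitat segmentation -> per-patient feature extraction
-> group comparison, ROC, and VIF-screened stepwise logistic IDH models
with LOOCV -> median-split PFS survival analysis -> CSV reports plus a
run manifest.  An optional contrast-enhanced-subgroup pass repeats
clustering-through-stats after excluding no/mild-enhancement patients.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import habitats as hab
from . import nifti_io, stats
from . import survival as surv
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger(__name__)

CLINICAL_VARS = [
    "age", "sex_male", "frontal", "hemorrhage", "necrosis", "cysts", "edema",
    "ringlike_enhancement", "none_mild_enhancement",
]
HABITAT_FEATURES = [
    f"{stem}_h{h}" for h in (1, 2, 3) for stem in ("adc_mean", "ktrans_mean", "volume", "pvol")
]
VOI_FEATURES = ["adc_mean_voi", "ktrans_mean_voi", "volume_voi"]
MODEL_BLOCKS = {
    "CM": [],
    "TV": VOI_FEATURES,
    "H1": [c for c in HABITAT_FEATURES if c.endswith("_h1")],
    "H2": [c for c in HABITAT_FEATURES if c.endswith("_h2")],
    "H3": [c for c in HABITAT_FEATURES if c.endswith("_h3")],
    "AHs": HABITAT_FEATURES,
}
REFERENCE_MODEL = "AHs"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str, patient_ids: list[str] | None = None):
        self.stage = stage
        self.patient_ids = patient_ids or []
        suffix = f" (patients: {self.patient_ids})" if self.patient_ids else ""
        super().__init__(f"stage {stage!r} failed: {message}{suffix}")


@dataclass
class PipelineConfig:
    out_dir: str = "gliohab_run"
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None  # with cases/ and cohort.csv, when simulate=False
    k: int = 3
    seed: int = 0
    per_patient_cap: int | None = None
    standardize: bool = True
    screen_alpha: float = 0.05
    vif_max: float = 5.0
    loocv: bool = True
    enhanced_subgroup: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0 < self.screen_alpha < 1):
            raise ValueError("screen_alpha must lie in (0, 1)")
        if self.vif_max <= 1:
            raise ValueError("vif_max must exceed 1")
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)

    def to_yaml_dict(self) -> dict:
        d = asdict(self)
        return yaml.safe_load(yaml.safe_dump(d, default_flow_style=False)) or d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            for key in ("habitat_intensity",):
                if key in raw["cohort"]:
                    raw["cohort"][key] = {
                        g: {int(h): v for h, v in m.items()}
                        for g, m in raw["cohort"][key].items()
                    }
            if "who_grade_probs" in raw["cohort"]:
                raw["cohort"]["who_grade_probs"] = {
                    g: {int(k): v for k, v in m.items()}
                    for g, m in raw["cohort"]["who_grade_probs"].items()
                }
            raw["cohort"] = CohortConfig(**raw["cohort"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig, out: Path):
    cohort = generate_cohort(config.cohort)
    cases_dir = out / "cases"
    for case in cohort.cases:
        nifti_io.write_case(case, cases_dir / case.patient_id,
                            truth_labels=cohort.truth[case.patient_id].labels,
                            voxel_size_mm=config.cohort.voxel_size_mm)
    cohort.cohort_table.to_csv(out / "cohort.csv", index=False)
    return cohort.cases, cohort.cohort_table


def stage_load(config: PipelineConfig):
    root = Path(config.input_dir)
    cases = [nifti_io.read_case(p) for p in nifti_io.list_case_dirs(root / "cases")]
    table = pd.read_csv(root / "cohort.csv")
    return cases, table


def stage_cluster(cases, config: PipelineConfig, out: Path):
    table = hab.build_voxel_table(cases, per_patient_cap=config.per_patient_cap,
                                  seed=config.seed, standardize=config.standardize)
    model = hab.kmeans_fit(table, k=config.k, seed=config.seed)
    if config.k == 3:
        model = hab.assign_habitat_labels(model)
    else:  # habitat semantics undefined; identity labeling
        from dataclasses import replace
        model = replace(model, label_map={i: i + 1 for i in range(config.k)})
    model.save(out / "habitat_model.yaml")
    labels = {}
    for case in cases:
        lab = hab.segment_case(case, model)
        labels[case.patient_id] = lab
        nifti_io.write_labels(lab, out / "cases" / case.patient_id,
                              case.voxel_volume ** (1 / 3))
    return model, labels


def stage_features(cases, labels, cohort_table, out: Path):
    records = [feat.extract_features(c, labels[c.patient_id]) for c in cases]
    table = feat.cohort_feature_table(records, cohort_table)
    table.to_csv(out / "features.csv", index=False)
    feat.genotype_summary(table).to_csv(out / "genotype_summary.csv", index=False)
    return table


def _derive_design_columns(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    t["sex_male"] = (t["sex"] == "M").astype(int)
    t["frontal"] = (t["location"] == "frontal").astype(int)
    t["ringlike_enhancement"] = (t["enhancement"] == "ringlike").astype(int)
    t["none_mild_enhancement"] = (t["enhancement"] == "none_mild").astype(int)
    return t


def stage_stats(analysis: pd.DataFrame, config: PipelineConfig, out: Path):
    """Group comparisons, single-feature ROC, and the six logistic models."""
    t = _derive_design_columns(analysis)
    y_all = t["idh_mutant"].to_numpy()

    comparisons = []
    for col in feat.FEATURE_COLUMNS:
        try:
            gc = stats.compare_groups(t[col], t["genotype"], feature=col)
            comparisons.append({
                "feature": col, "test": gc.test, "statistic": gc.statistic,
                "p": gc.pvalue,
                **{f"{g}_{k}": v for g, (m, s, n) in gc.group_stats.items()
                   for k, v in (("mean", m), ("sd", s), ("n", n))},
            })
        except ValueError as exc:
            log.info("compare_groups skipped %s: %s", col, exc)
    pd.DataFrame(comparisons).to_csv(out / "group_comparisons.csv", index=False)

    rocs = []
    for col in feat.FEATURE_COLUMNS:
        sub = t.dropna(subset=[col])
        # positive class: IDH wild-type (higher K^trans); orientation auto
        r = stats.roc_auc(sub[col], 1 - sub["idh_mutant"], positive_label=1)
        rocs.append({"feature": col, "auc": r.auc, "ci_low": r.ci[0], "ci_high": r.ci[1],
                     "p": r.pvalue, "sensitivity": r.sensitivity,
                     "specificity": r.specificity, "cutoff": r.cutoff,
                     "orientation": r.orientation})
    pd.DataFrame(rocs).to_csv(out / "roc_features.csv", index=False)

    coef_rows, perf_rows, fitted = [], [], {}
    for name, block in MODEL_BLOCKS.items():
        candidates = CLINICAL_VARS + block
        sub = t.dropna(subset=candidates)
        if len(sub) < len(t):
            log.info("model %s: %d patients dropped for missing features",
                     name, len(t) - len(sub))
        design, y = sub[candidates].astype(float), sub["idh_mutant"].to_numpy()
        uni = stats.univariable_screen(design, y, alpha=config.screen_alpha)
        kept = list(uni.index[uni["selected"]])
        vifs = stats.vif(design[kept]) if len(kept) >= 2 else pd.Series(1.0, index=kept)
        kept = stats.screen_vif(design[kept], config.vif_max) if len(kept) >= 2 else kept
        fit, path = stats.stepwise_select(design[kept], y, stay_p=config.screen_alpha)
        for var in candidates:
            row = {"model": name, "variable": var,
                   "uni_OR": uni.loc[var, "OR"], "uni_ci_low": uni.loc[var, "ci_low"],
                   "uni_ci_high": uni.loc[var, "ci_high"], "uni_p": uni.loc[var, "p"],
                   "vif": vifs.get(var, np.nan)}
            if var in fit.variables:
                row.update(multi_OR=fit.or_table.loc[var, "OR"],
                           multi_ci_low=fit.or_table.loc[var, "ci_low"],
                           multi_ci_high=fit.or_table.loc[var, "ci_high"],
                           multi_p=fit.or_table.loc[var, "p"])
            coef_rows.append(row)
        roc = stats.roc_auc(fit.fitted_prob, y, positive_label=1, orientation=1)
        hl_chi2, hl_p, _ = stats.hosmer_lemeshow(fit.fitted_prob, y) \
            if len(y) >= 20 else (np.nan, np.nan, None)
        perf = {"model": name, "n": len(sub), "variables": "+".join(fit.variables),
                "dropped": "+".join(path),
                "auc": roc.auc, "ci_low": roc.ci[0], "ci_high": roc.ci[1],
                "auc_p": roc.pvalue, "sensitivity_pct": 100 * roc.sensitivity,
                "specificity_pct": 100 * roc.specificity,
                "accuracy_pct": 100 * roc.accuracy,
                "hl_chi2": hl_chi2, "hl_p": hl_p}
        if config.loocv and fit.variables:
            cv = stats.loocv_auc(design, y, fit.variables)
            perf.update(cv_auc=cv.roc.auc, cv_ci_low=cv.roc.ci[0], cv_ci_high=cv.roc.ci[1])
        fitted[name] = (roc, sub.index)
        perf_rows.append(perf)

    ref_roc, ref_idx = fitted[REFERENCE_MODEL]
    for row in perf_rows:
        name = row["model"]
        if name == REFERENCE_MODEL:
            row["delong_p_vs_ref"] = np.nan
            continue
        roc, idx = fitted[name]
        paired = idx.equals(ref_idx)
        try:
            cmp = stats.delong_compare(roc, ref_roc, paired=paired)
            row["delong_p_vs_ref"] = cmp.pvalue
        except ValueError:
            row["delong_p_vs_ref"] = np.nan
    perf = pd.DataFrame(perf_rows)
    pd.DataFrame(coef_rows).to_csv(out / "model_coefficients.csv", index=False)
    perf.to_csv(out / "model_performance.csv", index=False)
    return perf


def stage_survival(analysis: pd.DataFrame, out: Path):
    res = surv.habitat_survival_analysis(analysis, HABITAT_FEATURES)
    res.to_csv(out / "survival.csv", index=False)
    curves = []
    for genotype, sub in analysis.groupby("genotype"):
        try:
            labels, _ = surv.median_split(sub["pvol_h2"].to_numpy())
            km = surv.kaplan_meier(sub["pfs_months"], sub["progression"], labels)
            for curve in km.curves.values():
                tab = curve.table.copy()
                tab.insert(0, "subgroup", curve.group)
                tab.insert(0, "genotype", genotype)
                curves.append(tab)
        except ValueError as exc:
            log.info("KM export skipped for %s: %s", genotype, exc)
    if curves:
        pd.concat(curves, ignore_index=True).to_csv(out / "km_curves.csv", index=False)
    return res


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.to_yaml_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_manifest(config: PipelineConfig, out: Path, outputs: list[str]) -> None:
    import lifelines, nibabel, scipy, sklearn, statsmodels

    from . import __version__

    manifest = {
        "config": config.to_yaml_dict(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "outputs": outputs,
        "versions": {
            "gliohab": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
            "lifelines": lifelines.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage in order; outputs land under ``config.out_dir``.

    A stage failure aborts the run with the stage name (and offending
    patient ids where known).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _run(stage, fn, *args):
        try:
            return fn(*args)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

    if config.simulate:
        cases, cohort_table = _run("simulate", stage_simulate, config, out)
    else:
        cases, cohort_table = _run("load", stage_load, config)
    model, labels = _run("cluster", stage_cluster, cases, config, out)
    analysis = _run("features", stage_features, cases, labels, cohort_table, out)
    _run("stats", stage_stats, analysis, config, out)
    _run("survival", stage_survival, analysis, out)

    if config.enhanced_subgroup:
        keep = cohort_table.loc[cohort_table["enhancement"] != "none_mild", "patient_id"]
        sub_cases = [c for c in cases if c.patient_id in set(keep)]
        sub_table = cohort_table[cohort_table["patient_id"].isin(set(keep))].reset_index(drop=True)
        sub_out = out / "enhanced_subgroup"
        sub_out.mkdir(exist_ok=True)
        if len(sub_cases) >= 2 * (config.k + 1):
            _model, sub_labels = _run("subgroup-cluster", stage_cluster, sub_cases, config, sub_out)
            sub_analysis = _run("subgroup-features", stage_features, sub_cases, sub_labels,
                                sub_table, sub_out)
            _run("subgroup-stats", stage_stats, sub_analysis, config, sub_out)
        else:
            log.warning("enhanced subgroup too small (%d cases); skipped", len(sub_cases))

    outputs = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    _write_manifest(config, out, outputs)
    return {"out_dir": out, "manifest": out / "manifest.yaml"}
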