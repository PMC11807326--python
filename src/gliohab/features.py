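"""Per-patient quantitative habitat features.

For each habitat h in {1,2,3}: mean ADC (10^-6 mm^2/s), mean K^trans
(10^-3 min^-1), absolute volume (cm^3) and volume percentage pVol (%) of
the tumor VOI; plus the same intensity means and the total volume over
the whole VOI.  Empty habitats get volume 0, pVol 0 and undefined (NaN)
intensity means, which group statistics exclude listwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .habitats import ParametricCase

log = logging.getLogger(__name__)

HABITATS = (1, 2, 3)

#: Feature-table column order (after patient_id).
FEATURE_COLUMNS = [
    f"{stem}_h{h}" for h in HABITATS for stem in ("adc_mean", "ktrans_mean", "volume", "pvol")
] + ["adc_mean_voi", "ktrans_mean_voi", "volume_voi"]


@dataclass(frozen=True)
class HabitatFeatureRecord:
    patient_id: str
    adc_mean: dict[int, float]  # per habitat; NaN if empty
    ktrans_mean: dict[int, float]
    volume: dict[int, float]  # cm^3
    pvol: dict[int, float]  # % of VOI volume
    adc_mean_voi: float
    ktrans_mean_voi: float
    volume_voi: float  # cm^3

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"patient_id": self.patient_id}
        for h in HABITATS:
            row[f"adc_mean_h{h}"] = self.adc_mean[h]
            row[f"ktrans_mean_h{h}"] = self.ktrans_mean[h]
            row[f"volume_h{h}"] = self.volume[h]
            row[f"pvol_h{h}"] = self.pvol[h]
        row["adc_mean_voi"] = self.adc_mean_voi
        row["ktrans_mean_voi"] = self.ktrans_mean_voi
        row["volume_voi"] = self.volume_voi
        return row


def extract_features(case: ParametricCase, labels: np.ndarray) -> HabitatFeatureRecord:
    """Compute habitat and tumor-VOI features from a habitat label grid.

    ``labels`` must be 0 outside the mask and 1-3 (or 0 for excluded
    voxels) inside; volumes are voxel counts times voxel volume.
    """
    labels = np.asarray(labels)
    if labels.shape != case.mask.shape:
        raise ValueError(f"{case.patient_id}: label grid shape mismatch")
    if np.any((labels != 0) & ~case.mask):
        raise ValueError(f"{case.patient_id}: nonzero labels outside the tumor mask")
    n_mask = int(case.mask.sum())
    kt, adc = case.ktrans_map, case.adc_map
    vol_cm3 = case.voxel_volume / 1000.0
    adc_mean, kt_mean, volume, pvol = {}, {}, {}, {}
    for h in HABITATS:
        sel = labels == h
        n_h = int(sel.sum())
        volume[h] = n_h * vol_cm3
        pvol[h] = 100.0 * n_h / n_mask
        if n_h == 0:
            log.info("extract_features %s: habitat %d empty", case.patient_id, h)
            adc_mean[h] = float("nan")
            kt_mean[h] = float("nan")
        else:
            adc_mean[h] = float(adc[sel].mean())
            kt_mean[h] = float(kt[sel].mean())
    return HabitatFeatureRecord(
        patient_id=case.patient_id,
        adc_mean=adc_mean,
        ktrans_mean=kt_mean,
        volume=volume,
        pvol=pvol,
        adc_mean_voi=float(adc[case.mask].mean()),
        ktrans_mean_voi=float(kt[case.mask].mean()),
        volume_voi=n_mask * vol_cm3,
    )


def features_frame(records: list[HabitatFeatureRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records], columns=["patient_id"] + FEATURE_COLUMNS)


def cohort_feature_table(
    records: list[HabitatFeatureRecord] | pd.DataFrame,
    cohort_table: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join features with the clinical cohort table on patient_id.

    Requires a one-to-one match; duplicate or unmatched ids raise with
    the offending id list.
    """
    feats = records if isinstance(records, pd.DataFrame) else features_frame(records)
    for name, frame in (("features", feats), ("cohort table", cohort_table)):
        dup = frame["patient_id"][frame["patient_id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate patient ids in {name}: {dup}")
    missing = sorted(
        set(feats["patient_id"]).symmetric_difference(set(cohort_table["patient_id"]))
    )
    if missing:
        raise ValueError(f"unmatched patient ids: {missing}")
    return feats.merge(cohort_table, on="patient_id", how="inner", validate="1:1")


def genotype_summary(table: pd.DataFrame, group_col: str = "genotype") -> pd.DataFrame:
    """Per-genotype mean +/- SD of every habitat/VOI feature.

    Undefined (NaN) means from empty habitats are excluded listwise per
    feature.  Layout: one row per feature, one (mean, sd, n) triple per
    genotype.
    """
    rows = []
    for col in FEATURE_COLUMNS:
        row: dict[str, float | str] = {"feature": col}
        for g, sub in table.groupby(group_col):
            vals = sub[col].dropna()
            row[f"{g}_mean"] = float(vals.mean())
            row[f"{g}_sd"] = float(vals.std(ddof=1))
            row[f"{g}_n"] = int(vals.size)
        rows.append(row)
    return pd.DataFrame(rows)
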