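"""Cohort-based habitat clustering of (K^trans, ADC) tumor voxels.

One k-means model (k=3 by default) is fitted on z-scored voxels pooled
across the whole cohort so that habitat definitions are shared between
patients, then each patient's tumor is segmented by nearest centroid.
Habitat semantics follow the centroids in original units:

* Habitat 3 — highest K^trans ("hyper-vasopermeability"),
* Habitat 1 — of the rest, lower ADC ("hypo-vasopermeability,
  hyper-cellularity"),
* Habitat 2 — of the rest, higher ADC ("hypo-vasopermeability,
  hypo-cellularity").

Channels are pooled-z-scored before clustering: raw K^trans (~10-200
x10^-3 min^-1) and ADC (~900-1700 x10^-6 mm^2/s) live on scales an order
of magnitude apart, and unscaled Euclidean k-means would be driven almost
entirely by ADC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

CHANNELS = ("ktrans", "adc")


@dataclass(frozen=True)
class ParametricCase:
    """One patient's co-registered parametric maps and tumor mask.

    ``ktrans_map`` is in 10^-3 min^-1, ``adc_map`` in 10^-6 mm^2/s,
    ``voxel_volume`` in mm^3.
    """

    patient_id: str
    ktrans_map: np.ndarray
    adc_map: np.ndarray
    mask: np.ndarray
    voxel_volume: float

    def __post_init__(self) -> None:
        if not (self.ktrans_map.shape == self.adc_map.shape == self.mask.shape):
            raise ValueError(
                f"{self.patient_id}: grid shapes differ "
                f"{self.ktrans_map.shape}/{self.adc_map.shape}/{self.mask.shape}"
            )
        if self.voxel_volume <= 0:
            raise ValueError(f"{self.patient_id}: voxel_volume must be positive")
        object.__setattr__(self, "mask", np.asarray(self.mask).astype(bool))
        if not self.mask.any():
            raise ValueError(f"{self.patient_id}: empty tumor mask")


@dataclass(frozen=True)
class ChannelScaling:
    """Pooled per-channel mean/SD used to z-score (ktrans, adc)."""

    ktrans_mean: float
    ktrans_sd: float
    adc_mean: float
    adc_sd: float

    def transform(self, ktrans: np.ndarray, adc: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [
                (np.asarray(ktrans, float) - self.ktrans_mean) / self.ktrans_sd,
                (np.asarray(adc, float) - self.adc_mean) / self.adc_sd,
            ]
        )

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        return np.column_stack(
            [
                z[:, 0] * self.ktrans_sd + self.ktrans_mean,
                z[:, 1] * self.adc_sd + self.adc_mean,
            ]
        )


@dataclass(frozen=True)
class VoxelTable:
    """In-mask voxels pooled across the cohort, with z-scored channels."""

    records: pd.DataFrame  # patient_id, voxel_index, ktrans, adc, z_ktrans, z_adc
    scaling: ChannelScaling

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class HabitatModel:
    """Fitted cohort clustering model.

    ``centroids_std`` / ``centroids`` are (k, 2) arrays in (ktrans, adc)
    order, standardized and original units; ``label_map`` maps cluster
    index -> habitat number once :func:`assign_habitat_labels` has run.
    """

    k: int
    centroids_std: np.ndarray
    centroids: np.ndarray
    scaling: ChannelScaling
    seed: int
    inertia: float
    label_map: dict[int, int] | None = None

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "centroids_std": np.asarray(self.centroids_std).tolist(),
            "centroids": np.asarray(self.centroids).tolist(),
            "scaling": {
                "ktrans_mean": self.scaling.ktrans_mean,
                "ktrans_sd": self.scaling.ktrans_sd,
                "adc_mean": self.scaling.adc_mean,
                "adc_sd": self.scaling.adc_sd,
            },
            "seed": int(self.seed),
            "inertia": float(self.inertia),
            "label_map": None
            if self.label_map is None
            else {int(c): int(h) for c, h in self.label_map.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "HabitatModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            k=d["k"],
            centroids_std=np.asarray(d["centroids_std"], float),
            centroids=np.asarray(d["centroids"], float),
            scaling=ChannelScaling(**d["scaling"]),
            seed=d["seed"],
            inertia=d["inertia"],
            label_map=None
            if d["label_map"] is None
            else {int(c): int(h) for c, h in d["label_map"].items()},
        )


def build_voxel_table(
    cases: list[ParametricCase],
    per_patient_cap: int | None = None,
    seed: int = 0,
    standardize: bool = True,
) -> VoxelTable:
    """Pool in-mask voxels across the cohort and z-score each channel.

    With ``per_patient_cap`` set, each patient contributes at most that
    many voxels, subsampled uniformly without replacement under the
    cohort seed.  Standardization statistics are computed on the pooled
    (possibly capped) table.
    """
    if not cases:
        raise ValueError("at least one case is required")
    rng = np.random.default_rng(seed)
    frames = []
    for case in cases:
        idx = np.flatnonzero(case.mask.ravel())
        if idx.size == 0:  # unreachable through ParametricCase, defensive
            raise ValueError(f"{case.patient_id}: empty tumor mask")
        if per_patient_cap is not None and idx.size > per_patient_cap:
            idx = np.sort(rng.choice(idx, size=per_patient_cap, replace=False))
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": case.patient_id,
                    "voxel_index": idx,
                    "ktrans": case.ktrans_map.ravel()[idx],
                    "adc": case.adc_map.ravel()[idx],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    if not standardize:  # cluster in raw units (identity scaling)
        scaling = ChannelScaling(0.0, 1.0, 0.0, 1.0)
        records["z_ktrans"] = records["ktrans"].astype(float)
        records["z_adc"] = records["adc"].astype(float)
        return VoxelTable(records=records, scaling=scaling)
    scaling = ChannelScaling(
        ktrans_mean=float(records["ktrans"].mean()),
        ktrans_sd=float(records["ktrans"].std(ddof=0)),
        adc_mean=float(records["adc"].mean()),
        adc_sd=float(records["adc"].std(ddof=0)),
    )
    z = scaling.transform(records["ktrans"].to_numpy(), records["adc"].to_numpy())
    records["z_ktrans"], records["z_adc"] = z[:, 0], z[:, 1]
    return VoxelTable(records=records, scaling=scaling)


def kmeans_fit(table: VoxelTable, k: int = 3, seed: int = 0, n_init: int = 10) -> HabitatModel:
    """Lloyd k-means with k-means++ restarts on the standardized voxels."""
    z = table.records[["z_ktrans", "z_adc"]].to_numpy()
    if np.unique(z, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct voxel values")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=300, tol=1e-4,
                random_state=seed)
    km.fit(z)
    return HabitatModel(
        k=k,
        centroids_std=km.cluster_centers_.copy(),
        centroids=table.scaling.inverse(km.cluster_centers_),
        scaling=table.scaling,
        seed=seed,
        inertia=float(km.inertia_),
    )


def assign_habitat_labels(model: HabitatModel) -> HabitatModel:
    """Map cluster indices to habitats 1-3 from original-unit centroids.

    The cluster with the highest K^trans centroid becomes Habitat 3; of
    the remaining two, the lower-ADC centroid is Habitat 1 and the
    higher-ADC one Habitat 2.  A K^trans tie for the maximum is broken
    toward the higher-ADC cluster and logged.
    """
    if model.k != 3:
        raise ValueError("habitat semantics are defined for k=3")
    c = np.asarray(model.centroids, float)
    kt, adc = c[:, 0], c[:, 1]
    top = np.flatnonzero(kt == kt.max())
    if top.size > 1:
        log.warning("assign_habitat_labels: K^trans centroid tie broken by higher ADC")
        h3 = int(top[np.argmax(adc[top])])
    else:
        h3 = int(top[0])
    rest = [i for i in range(3) if i != h3]
    rest.sort(key=lambda i: adc[i])
    label_map = {rest[0]: 1, rest[1]: 2, h3: 3}
    return replace(model, label_map=label_map)


def segment_case(case: ParametricCase, model: HabitatModel) -> np.ndarray:
    """Assign each in-mask voxel to its nearest habitat centroid.

    Returns an integer grid: 0 outside the mask, habitat 1-3 inside.
    Distances are Euclidean in the model's standardized space; exact ties
    go to the lowest cluster index.  Non-finite voxels stay unlabeled.
    """
    if model.label_map is None:
        raise ValueError("model must be labeled (assign_habitat_labels) before segmentation")
    labels = np.zeros(case.mask.shape, dtype=np.int16)
    idx = np.flatnonzero(case.mask.ravel())
    kt = case.ktrans_map.ravel()[idx]
    adc = case.adc_map.ravel()[idx]
    finite = np.isfinite(kt) & np.isfinite(adc)
    if not finite.all():
        log.warning(
            "segment_case %s: excluded %d non-finite voxels", case.patient_id,
            int((~finite).sum()),
        )
    z = model.scaling.transform(kt[finite], adc[finite])
    d2 = ((z[:, None, :] - model.centroids_std[None, :, :]) ** 2).sum(axis=2)
    cluster = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    habitat = np.array([model.label_map[c] for c in range(model.k)], dtype=np.int16)
    flat = labels.ravel()
    flat[idx[finite]] = habitat[cluster]
    return flat.reshape(case.mask.shape)
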