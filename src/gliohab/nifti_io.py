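"""NIfTI input/output for parametric cases and habitat label maps.

Cases are stored one directory per patient containing ``ktrans.nii.gz``,
``adc.nii.gz``, ``mask.nii.gz`` and optionally ``truth_labels.nii.gz``;
grids must be pre-aligned (shape and affine are checked, nothing is
resampled here).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .habitats import ParametricCase

AFFINE_TOL = 1e-4
CASE_FILES = {"ktrans": "ktrans.nii.gz", "adc": "adc.nii.gz", "mask": "mask.nii.gz"}


def voxel_volume_mm3(img: nib.Nifti1Image) -> float:
    """Voxel volume from the affine (mm^3)."""
    return float(abs(np.linalg.det(img.affine[:3, :3])))


def write_case(case: ParametricCase, case_dir, truth_labels: np.ndarray | None = None,
               voxel_size_mm: float | None = None) -> Path:
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    edge = voxel_size_mm if voxel_size_mm is not None else case.voxel_volume ** (1 / 3)
    affine = np.diag([edge, edge, edge, 1.0])
    nib.save(nib.Nifti1Image(case.ktrans_map.astype(np.float32), affine),
             case_dir / CASE_FILES["ktrans"])
    nib.save(nib.Nifti1Image(case.adc_map.astype(np.float32), affine),
             case_dir / CASE_FILES["adc"])
    nib.save(nib.Nifti1Image(case.mask.astype(np.uint8), affine), case_dir / CASE_FILES["mask"])
    if truth_labels is not None:
        nib.save(nib.Nifti1Image(np.asarray(truth_labels, dtype=np.int16), affine),
                 case_dir / "truth_labels.nii.gz")
    return case_dir


def read_case(case_dir, patient_id: str | None = None) -> ParametricCase:
    """Load a case directory into a :class:`ParametricCase`.

    Enforces identical shapes and affines (to a small tolerance) across
    the three images; the voxel volume comes from the affine.
    """
    case_dir = Path(case_dir)
    imgs = {}
    for key, fname in CASE_FILES.items():
        path = case_dir / fname
        if not path.exists():
            raise FileNotFoundError(f"{case_dir}: missing {fname}")
        imgs[key] = nib.load(path)
    shapes = {k: im.shape for k, im in imgs.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"{case_dir}: grid shapes differ: {shapes}")
    ref = imgs["ktrans"].affine
    for key, im in imgs.items():
        if not np.allclose(im.affine, ref, atol=AFFINE_TOL):
            raise ValueError(f"{case_dir}: affine mismatch for {key} (no resampling performed)")
    return ParametricCase(
        patient_id=patient_id or case_dir.name,
        ktrans_map=np.asarray(imgs["ktrans"].dataobj, dtype=float),
        adc_map=np.asarray(imgs["adc"].dataobj, dtype=float),
        mask=np.asarray(imgs["mask"].dataobj) > 0,
        voxel_volume=voxel_volume_mm3(imgs["ktrans"]),
    )


def write_labels(labels: np.ndarray, case_dir, voxel_size_mm: float) -> Path:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    Path(case_dir).mkdir(parents=True, exist_ok=True)
    path = Path(case_dir) / "habitat_labels.nii.gz"
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), path)
    return path


def list_case_dirs(root) -> list[Path]:
    root = Path(root)
    return sorted(p for p in root.iterdir() if p.is_dir() and (p / CASE_FILES["mask"]).exists())
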