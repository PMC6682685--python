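"""NIfTI / CSV input-output and feature-table assembly."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .types import MODALITIES, SlicePatch, VolumeSet


def _affine(spacing) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def save_volume_set(vs: VolumeSet, out_dir: Path) -> None:
    """Write one patient's volumes and masks as RAS-oriented NIfTI-1."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(vs.spacing)
    for m, vol in vs.volumes.items():
        nib.save(
            nib.Nifti1Image(vol.astype(np.float32), aff),
            out_dir / f"{vs.patient_id}_{m}.nii.gz",
        )
    nib.save(
        nib.Nifti1Image(vs.brain_mask.astype(np.uint8), aff),
        out_dir / f"{vs.patient_id}_brain_mask.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(vs.tumor_mask.astype(np.uint8), aff),
        out_dir / f"{vs.patient_id}_tumor_mask.nii.gz",
    )


def save_cohort(
    cohort: Sequence[VolumeSet], table: pd.DataFrame, out_dir: Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for vs in cohort:
        save_volume_set(vs, out_dir)
    table.to_csv(out_dir / "labels.csv", index=False)


def load_volume_set(
    in_dir: Path, patient_id: str, meta: Dict
) -> VolumeSet:
    in_dir = Path(in_dir)
    volumes = {}
    spacing = (1.0, 1.0, 1.0)
    for m in MODALITIES:
        img = nib.load(in_dir / f"{patient_id}_{m}.nii.gz")
        volumes[m] = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    brain = np.asarray(
        nib.load(in_dir / f"{patient_id}_brain_mask.nii.gz").dataobj
    ) > 0
    tumor = np.asarray(
        nib.load(in_dir / f"{patient_id}_tumor_mask.nii.gz").dataobj
    ) > 0
    return VolumeSet(
        patient_id=patient_id,
        volumes=volumes,
        spacing=spacing,
        brain_mask=brain,
        tumor_mask=tumor,
        label=int(meta["label"]),
        age=float(meta.get("age", 50.0)),
        sex=str(meta.get("sex", "F")),
        kps=int(meta.get("kps", 90)),
    )


def load_cohort(in_dir: Path) -> Tuple[List[VolumeSet], pd.DataFrame]:
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "labels.csv")
    cohort = [
        load_volume_set(in_dir, row["patient_id"], row.to_dict())
        for _, row in table.iterrows()
    ]
    return cohort, table


def feature_table(
    patches: Sequence[SlicePatch],
    extractor: Callable[[SlicePatch], Dict[str, float]],
    perturbation_id: Optional[str] = None,
) -> pd.DataFrame:
    """One row of named features per patch, with provenance columns."""
    rows = []
    for sp in patches:
        row = {
            "patient_id": sp.patient_id,
            "slice_index": sp.slice_index,
            "label": sp.label,
        }
        if perturbation_id is not None:
            row["perturbation_id"] = perturbation_id
        row.update(extractor(sp))
        rows.append(row)
    return pd.DataFrame(rows)


def slice_manifest(patches: Sequence[SlicePatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [sp.patient_id for sp in patches],
            "slice_index": [sp.slice_index for sp in patches],
            "label": [sp.label for sp in patches],
            "area": [int(sp.mask.sum()) for sp in patches],
        }
    )


def file_hashes(paths: Sequence[Path]) -> Dict[str, str]:
    out = {}
    for p in paths:
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        out[str(p)] = h
    return out


def write_manifest(paths: Sequence[Path], out_path: Path) -> None:
    Path(out_path).write_text(json.dumps(file_hashes(paths), indent=2))
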