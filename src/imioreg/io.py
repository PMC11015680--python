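"""On-disk formats: NIfTI images/masks/fields, CSV tables, JSON manifests.

NIfTI is the canonical image format (DICOM is read-only input).  Arrays
are stored ``[row, col]`` with the voxel size in the header zooms; voxel
indices are 0-based with the physical origin at the centre of voxel
(0, 0).  Displacement fields are 3D NIfTI volumes of shape (H, W, 2)
holding mm-valued (row, col) vector components, tagged in the header
description.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import CTSlice, DisplacementField, MaskSet

_FIELD_TAG = b"dispfield_mm"


def write_slice(ct: CTSlice, path) -> None:
    affine = np.diag([ct.spacing_mm[0], ct.spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(ct.pixels, dtype=np.float32), affine)
    img.header.set_zooms((ct.spacing_mm[0], ct.spacing_mm[1]))
    nib.save(img, str(path))


def read_slice(path, slice_type: str, subject_id: str = "", sex: str = "M") -> CTSlice:
    """Read a single CT slice (NIfTI or single-frame DICOM) in HU."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        return _read_dicom(path, slice_type, subject_id, sex)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(
                f"expected single slice, got {data.shape[2]} slices in {path.name}"
            )
        data = data[..., 0]
    if data.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {data.shape} in {path.name}")
    zooms = img.header.get_zooms()[:2]
    return CTSlice(
        pixels=np.asarray(data, dtype=float),
        spacing_mm=(float(zooms[0]), float(zooms[1])),
        slice_type=slice_type,
        subject_id=subject_id,
        sex=sex,
    )


def _read_dicom(path, slice_type, subject_id, sex) -> CTSlice:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"expected single slice, got shape {arr.shape} in {path.name}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr.astype(float) * slope + intercept
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    return CTSlice(
        pixels=hu,
        spacing_mm=(float(spacing[0]), float(spacing[1])),
        slice_type=slice_type,
        subject_id=subject_id or str(getattr(ds, "PatientID", "")),
        sex=sex,
    )


def write_mask(mask: np.ndarray, spacing_mm, path) -> None:
    affine = np.diag([spacing_mm[0], spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[..., 0]
    return data.astype(bool)


def write_field(field: DisplacementField, path) -> None:
    affine = np.diag([field.spacing_mm[0], field.spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(field.vectors.astype(np.float64), affine)
    img.header["descrip"] = _FIELD_TAG
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3 or data.shape[2] != 2:
        raise ValueError(f"not a displacement field: shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    return DisplacementField(data.astype(float), (float(zooms[0]), float(zooms[1])))


def write_measurements(meas: pd.DataFrame, path) -> None:
    meas.to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def validate_manifest(path_or_dict) -> dict:
    """Schema-check a cohort manifest, reporting *all* violations at once."""
    if isinstance(path_or_dict, (str, Path)):
        base = Path(path_or_dict).parent
        with open(path_or_dict) as fh:
            manifest = json.load(fh)
    else:
        base = Path(".")
        manifest = path_or_dict

    problems: list[str] = []
    entries = manifest.get("entries")
    if not isinstance(entries, list) or not entries:
        problems.append("manifest has no 'entries' list")
        entries = []

    seen: set[str] = set()
    for k, entry in enumerate(entries):
        sid = entry.get("subject_id")
        if not sid:
            problems.append(f"entry {k}: missing subject_id")
            continue
        if sid in seen:
            problems.append(f"duplicate subject_id: {sid}")
        seen.add(sid)
        if entry.get("sex") not in ("M", "F"):
            problems.append(f"{sid}: sex must be M or F")
        for st, files in entry.get("slices", {}).items():
            for key in ("image",):
                if key not in files:
                    problems.append(f"{sid}/{st}: missing {key} path")
            for key, val in files.items():
                if key == "masks":
                    for name, p in val.items():
                        if not (base / p).exists():
                            problems.append(f"{sid}/{st}: missing mask file {p}")
                elif isinstance(val, str) and key != "flags" and not (base / val).exists():
                    problems.append(f"{sid}/{st}: missing {key} file {val}")

    for st, groups in manifest.get("template_ids", {}).items():
        for grp, tid in groups.items():
            if tid not in seen:
                problems.append(f"template {tid} ({st}, {grp}) not among entries")

    if problems:
        raise ManifestError(problems)
    return manifest


class ManifestError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("manifest validation failed:\n  " + "\n  ".join(problems))
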