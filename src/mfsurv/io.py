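"""Readers and writers for images, masks, clinical tables and feature CSVs.

Supported image formats: PNG/TIFF rasters (single slice) and NIfTI volumes
(``.nii`` / ``.nii.gz``, read as a slice stack with the slice axis first).
Masks are same-shape files whose nonzero pixels mark the region; they must be
two-valued.  Clinical tables are CSV with one row per subject.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .texture import GrayscaleROI

__all__ = [
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "load_subject",
    "read_clinical",
    "CLINICAL_COLUMNS",
]

CLINICAL_COLUMNS = ["subject_id", "age", "sex", "mgmt", "resection", "os_days", "event"]

_SEX_LEVELS = {"male", "female"}
_MGMT_LEVELS = {"methylated", "unmethylated"}
_RESECTION_LEVELS = {"total", "non-total"}


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path) -> np.ndarray:
    """Read a grayscale image as float; NIfTI volumes get slice axis first."""
    path = Path(path)
    if _is_nifti(path):
        arr = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
        arr = np.squeeze(arr)
        if arr.ndim == 3:
            arr = np.moveaxis(arr, -1, 0)
        if arr.ndim not in (2, 3):
            raise ValueError(f"{path}: expected a 2D or 3D volume, got shape {arr.shape}")
        return arr
    with Image.open(path) as img:
        if img.mode not in ("F", "I", "I;16", "L"):
            img = img.convert("F")
        return np.asarray(img, dtype=float)


def read_mask(path) -> np.ndarray:
    """Read a binary mask; nonzero = inside.  Rejects more than two values."""
    arr = read_image(path)
    values = np.unique(arr)
    if len(values) > 2:
        raise ValueError(f"{path}: mask has {len(values)} distinct values, expected 2")
    return arr > 0


def write_image(path, arr: np.ndarray) -> None:
    """Write a 2D float image (TIFF/PNG) or a 2D/3D NIfTI volume."""
    path = Path(path)
    arr = np.asarray(arr)
    if _is_nifti(path):
        data = np.moveaxis(arr, 0, -1) if arr.ndim == 3 else arr
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.eye(4)), str(path))
        return
    if arr.ndim != 2:
        raise ValueError("raster formats hold a single 2D slice; use NIfTI for stacks")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        Image.fromarray(arr.astype(np.float32), mode="F").save(path)
    elif suffix == ".png":
        lo, hi = float(arr.min()), float(arr.max())
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
        Image.fromarray((scaled * 65535).astype(np.uint16)).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def write_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    mask = np.asarray(mask).astype(bool)
    if _is_nifti(path):
        data = np.moveaxis(mask, 0, -1) if mask.ndim == 3 else mask
        nib.save(nib.Nifti1Image(data.astype(np.uint8), np.eye(4)), str(path))
        return
    if mask.ndim != 2:
        raise ValueError("raster formats hold a single 2D slice; use NIfTI for stacks")
    Image.fromarray(mask.astype(np.uint8) * 255).save(path)


def load_subject(
    image_path,
    roi_mask_path,
    reference_mask_path=None,
    subject_id: str | None = None,
) -> GrayscaleROI:
    """Load one subject's image + masks into a :class:`GrayscaleROI`.

    Shape mismatches raise ``ValueError`` naming the offending file.
    """
    intensity = read_image(image_path)
    roi_mask = read_mask(roi_mask_path)
    if roi_mask.shape != intensity.shape:
        raise ValueError(
            f"{roi_mask_path}: mask shape {roi_mask.shape} != image shape {intensity.shape}"
        )
    reference = None
    if reference_mask_path is not None:
        reference = read_mask(reference_mask_path)
        if reference.shape != intensity.shape:
            raise ValueError(f"{reference_mask_path}: reference mask shape mismatch")
    if subject_id is None:
        subject_id = Path(image_path).name.split(".")[0]
    return GrayscaleROI(intensity, roi_mask, reference, subject_id=subject_id)


def read_clinical(path) -> pd.DataFrame:
    """Read and validate the clinical CSV.

    Required columns: subject_id, age, sex (male/female), mgmt
    (methylated/unmethylated), resection (total/non-total), os_days (> 0),
    event (0/1).
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if df[CLINICAL_COLUMNS].isna().any().any():
        raise ValueError("clinical table contains missing values")
    for col, levels in (("sex", _SEX_LEVELS), ("mgmt", _MGMT_LEVELS), ("resection", _RESECTION_LEVELS)):
        bad = set(df[col].unique()) - levels
        if bad:
            raise ValueError(f"column {col!r} has unexpected levels {sorted(bad)}; expected {sorted(levels)}")
    if (df["os_days"] <= 0).any():
        raise ValueError("os_days must be positive")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event must be 0 or 1")
    return df
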