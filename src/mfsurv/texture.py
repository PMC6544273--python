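"""Threshold-sweep Minkowski texture features of grayscale ROIs.

A grayscale region of interest (for instance the peritumoral T2-hyperintense
rim around a brain tumor) is normalized to [0, 1], binarized at ``L`` equally
spaced thresholds ``t_k = k/(L-1)`` and each binary image is summarized by its
Minkowski triple ``(A, U, X)``.  With the default ``L = 11`` this yields the
33-element feature vector ``A0..A10, P0..P10, G0..G10`` per subject.

Conventions:

* binarization keeps pixels with normalized intensity **strictly greater**
  than the threshold;
* the first image (``t = 0``) is defined as the whole ROI and the last
  (``t = 1``) as empty, so the area curve always runs from ``|ROI|`` to 0;
* multi-slice ROIs are handled by accumulating cell-complex counts across
  slices before applying the Minkowski formulas — by additivity this equals
  summing per-slice functionals and keeps one feature vector per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .minkowski import (
    CellComplexCounts,
    MinkowskiTriple,
    count_cell_complex,
    minkowski_from_counts,
)

__all__ = [
    "GrayscaleROI",
    "MFCurve",
    "threshold_grid",
    "feature_names",
    "normalize_roi",
    "binarize_at",
    "mf_sweep",
    "exclude_subregions",
    "extract_cohort_features",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS = 11


@dataclass
class GrayscaleROI:
    """A grayscale image (2D slice or 3D slice stack) with an ROI mask.

    ``reference_mask`` optionally marks normal-appearing tissue whose mean
    intensity is used as a normalization reference; it must be disjoint from
    the ROI.
    """

    intensity: np.ndarray
    roi_mask: np.ndarray
    reference_mask: np.ndarray | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask).astype(bool)
        if self.intensity.ndim not in (2, 3):
            raise ValueError("intensity must be a 2D slice or 3D slice stack")
        if self.intensity.shape != self.roi_mask.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != mask shape {self.roi_mask.shape}"
            )
        if self.reference_mask is not None:
            self.reference_mask = np.asarray(self.reference_mask).astype(bool)
            if self.reference_mask.shape != self.intensity.shape:
                raise ValueError("reference mask shape mismatch")
            if (self.reference_mask & self.roi_mask).any():
                raise ValueError("reference mask overlaps the ROI mask")

    @property
    def n_roi_pixels(self) -> int:
        return int(self.roi_mask.sum())


def threshold_grid(n_levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Equally spaced thresholds ``k/(n_levels-1)`` from 0 to 1."""
    if n_levels < 2:
        raise ValueError("need at least 2 threshold levels")
    return np.linspace(0.0, 1.0, n_levels)


def feature_names(n_levels: int = DEFAULT_LEVELS) -> list[str]:
    """Stable feature column names: A0..A{L-1}, P0.., G0.. ."""
    return (
        [f"A{k}" for k in range(n_levels)]
        + [f"P{k}" for k in range(n_levels)]
        + [f"G{k}" for k in range(n_levels)]
    )


@dataclass
class MFCurve:
    """Per-threshold Minkowski triples of one ROI."""

    levels: np.ndarray
    triples: list[MinkowskiTriple] = field(repr=False)

    @property
    def area(self) -> np.ndarray:
        return np.array([t.area for t in self.triples])

    @property
    def perimeter(self) -> np.ndarray:
        return np.array([t.perimeter for t in self.triples])

    @property
    def genus(self) -> np.ndarray:
        return np.array([t.genus for t in self.triples])

    @property
    def flat(self) -> np.ndarray:
        """3L-vector ordered A_0..A_{L-1}, U_0..U_{L-1}, X_0..X_{L-1}."""
        return np.concatenate([self.area, self.perimeter, self.genus])

    @property
    def names(self) -> list[str]:
        return feature_names(len(self.levels))


def normalize_roi(roi: GrayscaleROI) -> np.ndarray:
    """Normalize ROI intensities to [0, 1]; zero outside the ROI.

    If a reference mask is given, intensities are first divided by the
    reference-region mean, then min-max rescaled over the ROI.  A constant
    ROI maps to all zeros (only the threshold-0 image is then nonempty),
    which is a documented degenerate case, not an error.
    """
    if roi.n_roi_pixels == 0:
        raise ValueError("cannot normalize an empty ROI")
    vals = roi.intensity[roi.roi_mask].astype(float)
    if roi.reference_mask is not None:
        if not roi.reference_mask.any():
            raise ValueError("reference mask is empty")
        ref_mean = float(roi.intensity[roi.reference_mask].mean())
        if ref_mean == 0.0:
            raise ValueError("degenerate reference region: mean intensity is zero")
        vals = vals / ref_mean
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros(roi.intensity.shape, dtype=float)
    if hi > lo:
        out[roi.roi_mask] = (vals - lo) / (hi - lo)
    return out


def binarize_at(normalized: np.ndarray, roi_mask: np.ndarray, t: float) -> np.ndarray:
    """Binary image of ROI pixels with normalized intensity strictly above ``t``.

    Endpoint overrides: ``t = 0`` returns the whole ROI mask and ``t = 1``
    returns the empty mask, matching the sweep's boundary conventions.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    roi_mask = np.asarray(roi_mask).astype(bool)
    if t == 0.0:
        return roi_mask.copy()
    if t == 1.0:
        return np.zeros_like(roi_mask)
    return roi_mask & (np.asarray(normalized) > t)


def _slices(arr: np.ndarray):
    return [arr] if arr.ndim == 2 else list(arr)


def mf_sweep(roi: GrayscaleROI, n_levels: int = DEFAULT_LEVELS) -> MFCurve:
    """Minkowski triples of the ROI at each of ``n_levels`` thresholds.

    For slice stacks the cell-complex counts are accumulated across slices
    before applying the formulas (slices are disjoint, so this equals the sum
    of per-slice functionals).
    """
    levels = threshold_grid(n_levels)
    if roi.n_roi_pixels == 0:
        raise ValueError("cannot extract features from an empty ROI")
    normalized = normalize_roi(roi)
    norm_slices = _slices(normalized)
    mask_slices = _slices(roi.roi_mask)

    triples = []
    for t in levels:
        pix = edg = ver = 0
        for norm2d, mask2d in zip(norm_slices, mask_slices):
            c = count_cell_complex(binarize_at(norm2d, mask2d, float(t)))
            pix += c.n_pixels
            edg += c.n_edges
            ver += c.n_vertices
        total = CellComplexCounts(pix, edg, ver)
        triples.append(minkowski_from_counts(total))
    return MFCurve(levels=levels, triples=triples)


def exclude_subregions(
    roi_mask: np.ndarray,
    enhancing_mask: np.ndarray | None = None,
    necrosis_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Remove enhancing-tumor and necrosis pixels from an ROI mask."""
    roi = np.asarray(roi_mask).astype(bool)
    for other in (enhancing_mask, necrosis_mask):
        if other is not None:
            other = np.asarray(other).astype(bool)
            if other.shape != roi.shape:
                raise ValueError("exclusion mask shape mismatch")
            roi = roi & ~other
    return roi


def extract_cohort_features(
    rois: list[GrayscaleROI], n_levels: int = DEFAULT_LEVELS
) -> pd.DataFrame:
    """Feature table with one row per subject and 3L named columns.

    Row order follows the input list; subjects without an id are numbered by
    position.  An empty ROI raises with the offending subject id.
    """
    cols = feature_names(n_levels)
    rows, index = [], []
    for i, roi in enumerate(rois):
        sid = roi.subject_id if roi.subject_id is not None else str(i)
        if roi.n_roi_pixels == 0:
            raise ValueError(f"subject {sid!r}: ROI is empty after exclusions")
        rows.append(mf_sweep(roi, n_levels=n_levels).flat)
        index.append(sid)
    frame = pd.DataFrame(rows, columns=cols, index=pd.Index(index, name="subject_id"))
    return frame.astype(float)
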