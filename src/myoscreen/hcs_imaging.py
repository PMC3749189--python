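"""Segmentation of two-channel fields and myotube phenotype metrics.

A field carries a nuclear-stain channel and an MHC immunofluorescence
channel.  Nuclei and MHC-positive cell/myotube regions are segmented by
intensity thresholding and connected-component labeling; nuclei are
assigned to regions by centroid containment; a region is a myotube when it
is MHC-positive and contains at least ``min_nuclei_per_myotube`` nuclei
(default 3).  Per-well aggregation yields the four phenotype parameters:
percent myotubes, fusion index, myotube area and cell count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "FieldImage",
    "SegmentationParams",
    "LabelMap",
    "FieldMetrics",
    "WellMetrics",
    "UnthresholdableFieldError",
    "FailedAcquisitionError",
    "segment_nuclei",
    "segment_cells",
    "assign_nuclei",
    "field_metrics",
    "well_metrics",
]

INTENSITY_MAX = 65535


class UnthresholdableFieldError(ValueError):
    """Raised when automatic thresholding is requested on a flat channel."""


class FailedAcquisitionError(ValueError):
    """Raised when a well retains no valid field."""


@dataclass(frozen=True)
class FieldImage:
    """One imaging field: nuclear (hoechst) and MHC channels plus identity."""

    hoechst: np.ndarray
    mhc: np.ndarray
    plate_id: str = "plate1"
    well_id: str = "A01"
    field_index: int = 0

    def __post_init__(self) -> None:
        if self.hoechst.ndim != 2 or self.mhc.ndim != 2:
            raise ValueError("channels must be 2-D intensity grids")
        if self.hoechst.shape != self.mhc.shape:
            raise ValueError("hoechst and mhc channels must share one shape")
        for name, chan in (("hoechst", self.hoechst), ("mhc", self.mhc)):
            if chan.min() < 0 or chan.max() > INTENSITY_MAX:
                raise ValueError(f"{name} intensities outside [0, {INTENSITY_MAX}]")


@dataclass(frozen=True)
class SegmentationParams:
    nucleus_threshold_method: str = "otsu"
    nucleus_fixed_threshold: float | None = None
    min_nucleus_area_px: int = 12
    mhc_threshold_method: str = "otsu"
    mhc_fixed_threshold: float | None = None
    min_roi_area_px: int = 40

    def __post_init__(self) -> None:
        for method, fixed in (
            (self.nucleus_threshold_method, self.nucleus_fixed_threshold),
            (self.mhc_threshold_method, self.mhc_fixed_threshold),
        ):
            if method not in ("otsu", "fixed"):
                raise ValueError("threshold method must be 'otsu' or 'fixed'")
            if method == "fixed" and fixed is None:
                raise ValueError("fixed threshold method requires a threshold value")
        if self.min_nucleus_area_px <= 0 or self.min_roi_area_px <= 0:
            raise ValueError("minimum areas must be > 0")


@dataclass(frozen=True)
class LabelMap:
    """Connected-component partition of a thresholded channel."""

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        if self.n_objects != int(self.labels.max(initial=0)):
            raise ValueError("n_objects must equal the maximum label")


@dataclass(frozen=True)
class FieldMetrics:
    n_nuclei: int
    n_cell_rois: int
    per_roi_nucleus_count: tuple[int, ...]
    per_roi_is_mhc_positive: tuple[bool, ...]
    per_roi_area_px: tuple[int, ...] = ()
    min_nuclei_per_myotube: int = 3

    @property
    def myotube_flags(self) -> tuple[bool, ...]:
        return tuple(
            pos and cnt >= self.min_nuclei_per_myotube
            for pos, cnt in zip(
                self.per_roi_is_mhc_positive, self.per_roi_nucleus_count
            )
        )

    @property
    def n_myotubes(self) -> int:
        return sum(self.myotube_flags)

    @property
    def n_nuclei_in_myotubes(self) -> int:
        return sum(
            cnt
            for flag, cnt in zip(self.myotube_flags, self.per_roi_nucleus_count)
            if flag
        )

    @property
    def myotube_area_px(self) -> int:
        if not self.per_roi_area_px:
            return 0
        return sum(
            a for flag, a in zip(self.myotube_flags, self.per_roi_area_px) if flag
        )


@dataclass(frozen=True)
class WellMetrics:
    pct_myotubes: float
    fusion_index: float
    myotube_area_px: float
    cell_count: int
    n_valid_fields: int

    def __post_init__(self) -> None:
        if not 0 <= self.pct_myotubes <= 100:
            raise ValueError("pct_myotubes must lie in [0, 100]")
        if not 0 <= self.fusion_index <= 1:
            raise ValueError("fusion_index must lie in [0, 1]")


# ---------------------------------------------------------------------------


def _threshold(channel: np.ndarray, method: str, fixed: float | None) -> float:
    if method == "fixed":
        return float(fixed)  # type: ignore[arg-type]
    if channel.max() == channel.min():
        raise UnthresholdableFieldError(
            "channel is flat; otsu thresholding is undefined"
        )
    return float(threshold_otsu(channel))


def _label_channel(channel: np.ndarray, thr: float, min_area: int) -> LabelMap:
    fg = channel > thr
    labels = measure.label(fg, connectivity=2)
    if labels.max() > 0 and min_area > 1:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area)
        small = small[small > 0]
        if small.size:
            labels = measure.label(fg & ~np.isin(labels, small), connectivity=2)
    return LabelMap(labels=labels, n_objects=int(labels.max()))


def segment_nuclei(fld: FieldImage, params: SegmentationParams) -> LabelMap:
    """Label nuclei: supra-threshold nuclear-channel components above min area."""
    thr = _threshold(
        fld.hoechst, params.nucleus_threshold_method, params.nucleus_fixed_threshold
    )
    return _label_channel(fld.hoechst, thr, params.min_nucleus_area_px)


def segment_cells(fld: FieldImage, params: SegmentationParams) -> LabelMap:
    """Label MHC-positive cell/myotube ROIs above the minimum ROI area."""
    thr = _threshold(fld.mhc, params.mhc_threshold_method, params.mhc_fixed_threshold)
    return _label_channel(fld.mhc, thr, params.min_roi_area_px)


def assign_nuclei(nuclei: LabelMap, cells: LabelMap) -> np.ndarray:
    """Count nuclei per cell ROI by centroid containment.

    A nucleus belongs to the ROI whose label underlies its centroid pixel
    (centroid rounded to the nearest pixel); a centroid on background means
    the nucleus belongs to no ROI.  Returns an integer array of length
    ``cells.n_objects`` where entry ``k`` is the count for ROI label
    ``k + 1``.
    """
    if nuclei.labels.shape != cells.labels.shape:
        raise ValueError("nucleus and cell label maps must share one shape")
    counts = np.zeros(cells.n_objects, dtype=int)
    for prop in measure.regionprops(nuclei.labels):
        r, c = prop.centroid
        ri = min(max(int(round(r)), 0), cells.labels.shape[0] - 1)
        ci = min(max(int(round(c)), 0), cells.labels.shape[1] - 1)
        roi = cells.labels[ri, ci]
        if roi > 0:
            counts[roi - 1] += 1
    return counts


def field_metrics(
    fld: FieldImage,
    params: SegmentationParams,
    min_nuclei_per_myotube: int = 3,
) -> FieldMetrics:
    """Segment both channels and compute the per-field phenotype inputs."""
    nuclei = segment_nuclei(fld, params)
    cells = segment_cells(fld, params)
    counts = assign_nuclei(nuclei, cells)
    areas = tuple(
        int(a)
        for a in np.bincount(cells.labels.ravel(), minlength=cells.n_objects + 1)[1:]
    )
    return FieldMetrics(
        n_nuclei=nuclei.n_objects,
        n_cell_rois=cells.n_objects,
        per_roi_nucleus_count=tuple(int(c) for c in counts),
        per_roi_is_mhc_positive=tuple([True] * cells.n_objects),
        per_roi_area_px=areas,
        min_nuclei_per_myotube=min_nuclei_per_myotube,
    )


def well_metrics(
    fields: Sequence[FieldMetrics],
    min_nuclei_per_valid_field: int = 10,
) -> WellMetrics:
    """Aggregate field metrics into the four per-well phenotype parameters.

    Fields with fewer nuclei than ``min_nuclei_per_valid_field`` are
    excluded as failed acquisitions.  Over the remaining fields:
    ``cell_count`` is the total nucleus count, ``pct_myotubes`` the
    percentage of cell ROIs that are myotubes, ``fusion_index`` the
    fraction of nuclei residing in myotubes, and ``myotube_area_px`` the
    summed myotube area.
    """
    if not fields:
        raise ValueError("need at least one field")
    valid = [f for f in fields if f.n_nuclei >= min_nuclei_per_valid_field]
    if not valid:
        raise FailedAcquisitionError("no valid field in well (all below nucleus floor)")
    total_nuclei = sum(f.n_nuclei for f in valid)
    total_rois = sum(f.n_cell_rois for f in valid)
    total_myotubes = sum(f.n_myotubes for f in valid)
    nuclei_in_myotubes = sum(f.n_nuclei_in_myotubes for f in valid)
    area = float(sum(f.myotube_area_px for f in valid))
    pct = 100.0 * total_myotubes / total_rois if total_rois else 0.0
    fusion = nuclei_in_myotubes / total_nuclei if total_nuclei else 0.0
    return WellMetrics(
        pct_myotubes=pct,
        fusion_index=fusion,
        myotube_area_px=area,
        cell_count=total_nuclei,
        n_valid_fields=len(valid),
    )
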