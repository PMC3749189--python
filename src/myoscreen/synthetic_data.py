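"""Ground-truthed simulators for every stage of the screen.

Four generators, all seeded and deterministic:

* :func:`simulate_field` paints two-channel fields with mononucleated cells
  (nuclear disks) and multinucleated MHC-positive myotubes (thick bars with
  rounded ends) and returns the exact planted ground truth.
* :func:`simulate_plate` draws well-level phenotype metrics for a plate
  layout with per-reagent multiplicative effects and CV-parameterized noise.
* :func:`simulate_expression` builds quantification-cycle tables with a
  constitutive reference miRNA and a planted differential subset.
* :func:`simulate_stars` builds co-knockdown well tables with planted
  rescuing siRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hcs_imaging import INTENSITY_MAX, FieldImage
from .screen_analysis import PlateLayout

__all__ = [
    "ImageSimParams",
    "GroundTruth",
    "PlateSimParams",
    "FieldPackingError",
    "simulate_field",
    "simulate_plate",
    "simulate_expression",
    "simulate_stars",
    "CONTROL_ID",
]

#: Identifier used for control LNAs and control siRNAs in simulated tables.
CONTROL_ID = "control"

_MAX_PLACEMENT_TRIES = 1000


class FieldPackingError(RuntimeError):
    """Raised when requested objects cannot be placed without overlap."""


@dataclass(frozen=True)
class ImageSimParams:
    field_shape: tuple[int, int] = (512, 512)
    n_single_cells: int = 20
    myotube_specs: tuple[tuple[int, int], ...] = ()  # (nucleus_count, area_px)
    nucleus_radius_px: int = 6
    intensity_nucleus: float = 30000.0
    intensity_mhc: float = 25000.0
    intensity_background: float = 2000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_single_cells < 0 or self.nucleus_radius_px < 1:
            raise ValueError("counts and radii must be non-negative / positive")
        for k, area in self.myotube_specs:
            if k < 1:
                raise ValueError("every myotube spec needs nucleus_count >= 1")
            if area < 1:
                raise ValueError("myotube area must be positive")
        for val in (
            self.intensity_nucleus,
            self.intensity_mhc,
            self.intensity_background,
        ):
            if not 0 <= val <= INTENSITY_MAX:
                raise ValueError(f"intensity {val} outside [0, {INTENSITY_MAX}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact description of the planted objects of one field."""

    n_nuclei_total: int
    per_roi_nucleus_counts: tuple[int, ...]
    n_myotubes: int
    myotube_area_px: int
    n_mhc_rois: int = 0
    per_mhc_roi_nucleus_counts: tuple[int, ...] = ()
    per_mhc_roi_area_px: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if sum(self.per_roi_nucleus_counts) != self.n_nuclei_total:
            raise ValueError("per-ROI counts must sum to the nucleus total")
        if self.n_myotubes > len(self.per_roi_nucleus_counts):
            raise ValueError("more myotubes than ROIs")


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    inside = rr**2 + cc**2 <= radius**2
    return rr[inside], cc[inside]


def _capsule_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    half_len: float,
    radius: float,
) -> np.ndarray:
    """Pixels within ``radius`` of the axis segment (a bar with round ends)."""
    h, w = shape
    dr, dc = np.sin(angle), np.cos(angle)
    r0 = center[0] - half_len * dr
    c0 = center[1] - half_len * dc
    r1 = center[0] + half_len * dr
    c1 = center[1] + half_len * dc
    rmin = max(int(np.floor(min(r0, r1) - radius - 1)), 0)
    rmax = min(int(np.ceil(max(r0, r1) + radius + 1)), h - 1)
    cmin = max(int(np.floor(min(c0, c1) - radius - 1)), 0)
    cmax = min(int(np.ceil(max(c0, c1) + radius + 1)), w - 1)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    vr, vc = r1 - r0, c1 - c0
    seg_len2 = vr * vr + vc * vc
    if seg_len2 == 0:
        t = np.zeros_like(rr, dtype=float)
    else:
        t = np.clip(((rr - r0) * vr + (cc - c0) * vc) / seg_len2, 0.0, 1.0)
    dist2 = (rr - (r0 + t * vr)) ** 2 + (cc - (c0 + t * vc)) ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[rmin : rmax + 1, cmin : cmax + 1] = dist2 <= radius**2
    return mask


def _dilate1(mask: np.ndarray) -> np.ndarray:
    # 3x3 dilation keeps planted objects 8-disconnected from each other
    out = mask.copy()
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    out[1:, 1:] |= mask[:-1, :-1]
    out[1:, :-1] |= mask[:-1, 1:]
    out[:-1, 1:] |= mask[1:, :-1]
    out[:-1, :-1] |= mask[1:, 1:]
    return out


def simulate_field(params: ImageSimParams) -> tuple[FieldImage, GroundTruth]:
    """Paint one two-channel field and return it with its ground truth.

    Myotubes are placed first (largest objects), then mononucleated cells;
    no two planted objects overlap or touch.  Identical parameters produce
    bit-identical images.

    Raises
    ------
    FieldPackingError
        If an object cannot be placed within the bounded retry budget,
        i.e. the field is over-packed for the requested content.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_shape
    hoechst = np.full((h, w), params.intensity_background, dtype=float)
    mhc = np.full((h, w), params.intensity_background, dtype=float)
    occupancy = np.zeros((h, w), dtype=bool)
    r_nuc = params.nucleus_radius_px
    disk_rr, disk_cc = _disk_offsets(r_nuc)

    def paint_nucleus(center_r: int, center_c: int) -> None:
        rr = disk_rr + center_r
        cc = disk_cc + center_c
        hoechst[rr, cc] = params.intensity_nucleus

    mhc_areas: list[int] = []
    myotube_counts: list[int] = []
    spacing = 2 * r_nuc + 3  # keeps sibling nuclei 8-disconnected
    for idx, (k, area) in enumerate(params.myotube_specs):
        thickness = 2 * r_nuc + 6
        radius = thickness / 2.0
        # capsule area ~ 2*half_len*thickness + pi*radius^2; honor the nucleus chain
        half_len = max(
            (area - np.pi * radius**2) / (2.0 * thickness),
            (k - 1) * spacing / 2.0 + 1.0,
        )
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            angle = rng.uniform(0, np.pi)
            extent = half_len + radius + 2
            margin_r = abs(np.sin(angle)) * extent + radius + 2
            margin_c = abs(np.cos(angle)) * extent + radius + 2
            if 2 * margin_r >= h or 2 * margin_c >= w:
                continue
            cr = rng.uniform(margin_r, h - margin_r)
            cc_ = rng.uniform(margin_c, w - margin_c)
            mask = _capsule_mask((h, w), (cr, cc_), angle, half_len, radius)
            grown = _dilate1(mask)
            if (grown & occupancy).any():
                continue
            occupancy |= grown
            mhc[mask] = params.intensity_mhc
            mhc_areas.append(int(mask.sum()))
            # nuclei evenly spaced along the bar axis
            if k == 1:
                offsets = np.array([0.0])
            else:
                reach = min(half_len - 1.0, (k - 1) * spacing / 2.0)
                offsets = np.linspace(-reach, reach, k)
            for off in offsets:
                nr = int(round(cr + off * np.sin(angle)))
                nc = int(round(cc_ + off * np.cos(angle)))
                paint_nucleus(nr, nc)
            myotube_counts.append(k)
            placed = True
            break
        if not placed:
            raise FieldPackingError(
                f"field over-packed: myotube spec {idx} (nuclei={k}, area={area}) "
                f"could not be placed after {_MAX_PLACEMENT_TRIES} attempts"
            )

    for idx in range(params.n_single_cells):
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            cr = rng.integers(r_nuc + 2, h - r_nuc - 2)
            cc_ = rng.integers(r_nuc + 2, w - r_nuc - 2)
            mask = np.zeros((h, w), dtype=bool)
            mask[disk_rr + cr, disk_cc + cc_] = True
            grown = _dilate1(mask)
            if (grown & occupancy).any():
                continue
            occupancy |= grown
            paint_nucleus(cr, cc_)
            placed = True
            break
        if not placed:
            raise FieldPackingError(
                f"field over-packed: single cell {idx} could not be placed "
                f"after {_MAX_PLACEMENT_TRIES} attempts"
            )

    if params.noise_sd > 0:
        hoechst = hoechst + rng.normal(0.0, params.noise_sd, size=(h, w))
        mhc = mhc + rng.normal(0.0, params.noise_sd, size=(h, w))
    hoechst = np.clip(np.rint(hoechst), 0, INTENSITY_MAX).astype(np.uint16)
    mhc = np.clip(np.rint(mhc), 0, INTENSITY_MAX).astype(np.uint16)

    n_nuclei = params.n_single_cells + sum(myotube_counts)
    per_roi = tuple(myotube_counts) + (1,) * params.n_single_cells
    tube_flags = [k >= 3 for k in myotube_counts]
    truth = GroundTruth(
        n_nuclei_total=n_nuclei,
        per_roi_nucleus_counts=per_roi,
        n_myotubes=sum(tube_flags),
        myotube_area_px=sum(a for a, f in zip(mhc_areas, tube_flags) if f),
        n_mhc_rois=len(myotube_counts),
        per_mhc_roi_nucleus_counts=tuple(myotube_counts),
        per_mhc_roi_area_px=tuple(mhc_areas),
    )
    return FieldImage(hoechst=hoechst, mhc=mhc), truth


# ---------------------------------------------------------------------------
# plate simulation


@dataclass(frozen=True)
class PlateSimParams:
    layout: PlateLayout
    effect_map: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    control_mean_pct_myotubes: float = 40.0
    control_mean_cell_count: float = 2000.0
    well_noise_cv: float = 0.0
    n_fields_per_well: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.well_noise_cv < 0:
            raise ValueError("well_noise_cv must be >= 0")
        reagents = {e.reagent_id for e in self.layout.entries.values()}
        for reagent, (f_diff, f_count) in self.effect_map.items():
            if f_diff < 0 or f_count < 0:
                raise ValueError("effect factors must be >= 0")
            if reagent not in reagents:
                raise ValueError(f"effect_map reagent {reagent!r} not in layout")


def _effect_class(f_diff: float, f_count: float) -> str:
    if f_diff == 1.0 and f_count == 1.0:
        return "null"
    parts = []
    if f_diff < 1.0:
        parts.append("inhibited")
    elif f_diff > 1.0:
        parts.append("enhanced")
    if f_count < 1.0:
        parts.append("count_down")
    elif f_count > 1.0:
        parts.append("count_up")
    return "+".join(parts)


def simulate_plate(params: PlateSimParams) -> pd.DataFrame:
    """Draw well-level metrics for every well of the layout.

    Each sample well reads ``control_mean * effect * (1 + eps)`` with
    ``eps ~ Normal(0, well_noise_cv)``, truncated at zero.  Mock and
    negative-control wells always have unit effect factors.  The returned
    table carries the planted truth (``true_class`` and both factors).
    """
    layout = params.layout
    rng = np.random.default_rng(params.seed)
    rows = []
    for well_id, entry in layout.entries.items():
        if entry.role in ("mock", "neg_ctrl"):
            f_diff, f_count = 1.0, 1.0
        else:
            f_diff, f_count = params.effect_map.get(entry.reagent_id, (1.0, 1.0))
        eps = rng.normal(0.0, params.well_noise_cv, size=2) if params.well_noise_cv else np.zeros(2)
        pct = max(0.0, params.control_mean_pct_myotubes * f_diff * (1.0 + eps[0]))
        cnt = max(0.0, params.control_mean_cell_count * f_count * (1.0 + eps[1]))
        rows.append(
            {
                "well_id": well_id,
                "reagent_id": entry.reagent_id,
                "role": entry.role,
                "replicate": entry.replicate,
                "pct_myotubes": pct,
                "cell_count": cnt,
                "n_fields": params.n_fields_per_well,
                "true_class": _effect_class(f_diff, f_count),
                "true_diff_factor": f_diff,
                "true_count_factor": f_count,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    n_mirnas: int,
    differential_fraction: float,
    fold_range: tuple[float, float] = (2.0, 8.0),
    seed: int = 0,
    ct_noise_sd: float = 0.0,
    reference_id: str = "hsa-mir-16",
    reference_ct: float = 20.0,
    base_ct_range: tuple[float, float] = (22.0, 30.0),
) -> pd.DataFrame:
    """Simulate a two-condition Ct table with a planted differential subset.

    Exactly ``round(n_mirnas * differential_fraction)`` miRNAs receive a
    planted fold change (magnitude drawn from ``fold_range``, direction
    random) between proliferation and differentiation; the reference miRNA
    has a constant Ct in both conditions.  Truth columns ``true_fold`` and
    ``true_differential`` are included.
    """
    if not 0 <= differential_fraction <= 1:
        raise ValueError("differential_fraction must lie in [0, 1]")
    if fold_range[0] < 2:
        raise ValueError("fold_range minimum must be >= 2")
    if n_mirnas < 0 or ct_noise_sd < 0:
        raise ValueError("n_mirnas and ct_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_diff = round(n_mirnas * differential_fraction)
    diff_idx = set(rng.choice(n_mirnas, size=n_diff, replace=False)) if n_diff else set()
    rows = []

    def add(mirna: str, condition: str, ct: float, fold: float, is_diff: bool) -> None:
        noisy = ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0)
        rows.append(
            {
                "mirna_id": mirna,
                "condition": condition,
                "ct_target": noisy,
                "ct_reference": reference_ct,
                "true_fold": fold,
                "true_differential": is_diff,
            }
        )

    for i in range(n_mirnas):
        mirna = f"hsa-mir-sim{i:04d}"
        base_ct = rng.uniform(*base_ct_range)
        if i in diff_idx:
            magnitude = rng.uniform(*fold_range)
            fold = magnitude if rng.random() < 0.5 else 1.0 / magnitude
        else:
            fold = 1.0
        # higher expression in differentiation => lower Ct by log2(fold)
        add(mirna, "proliferation", base_ct, fold, i in diff_idx)
        add(mirna, "differentiation", base_ct - np.log2(fold), fold, i in diff_idx)
    for condition in ("proliferation", "differentiation"):
        add(reference_id, condition, reference_ct, 1.0, False)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# STarS simulation


def simulate_stars(
    mirna_id: str,
    genes: Sequence[str],
    rescuing: Mapping[str, set[int]],
    n_sirnas_per_gene: int = 4,
    seed: int = 0,
    n_replicates: int = 3,
    reference_fusion_index: float = 0.45,
    depressed_factor: float = 0.2,
    rescue_factor: float = 0.9,
    noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Simulate a co-knockdown (suppressor rescue) well table.

    Wells with the miRNA LNA plus a control siRNA read the depressed
    fusion index; wells with a planted rescuing siRNA are restored toward
    the reference; control-LNA + control-siRNA wells set the reference.
    siRNA ids are ``{gene}_si{j}`` with ``j`` in ``0..n_sirnas_per_gene-1``.
    """
    for gene, ids in rescuing.items():
        if gene not in genes:
            raise ValueError(f"rescuing gene {gene!r} not in gene list")
        for j in ids:
            if not 0 <= j < n_sirnas_per_gene:
                raise ValueError(
                    f"rescuing siRNA index {j} out of range for {gene!r}"
                )
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []

    def add(lna: str, sirna: str, gene: str, rescued: bool, level: float) -> None:
        for rep in range(1, n_replicates + 1):
            eps = rng.normal(0.0, noise_cv) if noise_cv else 0.0
            fi = float(np.clip(level * (1.0 + eps), 0.0, 1.0))
            rows.append(
                {
                    "lna_id": lna,
                    "sirna_id": sirna,
                    "gene": gene,
                    "replicate": rep,
                    "fusion_index": fi,
                    "true_rescue": rescued,
                }
            )

    ref = reference_fusion_index
    depressed = ref * depressed_factor
    add(CONTROL_ID, CONTROL_ID, CONTROL_ID, False, ref)
    add(mirna_id, CONTROL_ID, CONTROL_ID, False, depressed)
    for gene in genes:
        planted = rescuing.get(gene, set())
        for j in range(n_sirnas_per_gene):
            rescued = j in planted
            level = ref * rescue_factor if rescued else depressed
            add(mirna_id, f"{gene}_si{j}", gene, rescued, level)
    return pd.DataFrame(rows)
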