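"""RT-qPCR quantities and expression-versus-function comparison.

Fold changes follow the comparative-cycle (2^-ddCt) method against a
constitutive reference miRNA; differential expression uses the symmetric
ratio >= 2 rule; the module also houses knockdown efficiency, pulldown
enrichment ratios, dual-luciferase reporter normalization, and the
intersection of expression calls with functional hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "DifferentialCall",
    "harmonize_mirna_id",
    "ddct_fold_change",
    "differential_call",
    "call_differentials",
    "knockdown_efficiency",
    "intersect_hits",
    "tap_tar_enrichment",
    "reporter_ratio",
]


@dataclass(frozen=True)
class CtRecord:
    """Raw quantification cycles for one miRNA in one condition."""

    mirna_id: str
    condition: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {ct}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class DifferentialCall:
    mirna_id: str
    fold_change: float
    is_differential: bool


def harmonize_mirna_id(mirna_id: str) -> str:
    """Case-normalize a miRNA id (unifies hsa-mir / hsa-miR spellings)."""
    return mirna_id.strip().lower()


def ddct_fold_change(sample: CtRecord, calibrator: CtRecord) -> float:
    """Relative quantity 2^-(dCt_sample - dCt_calibrator), efficiency 2."""
    if harmonize_mirna_id(sample.mirna_id) != harmonize_mirna_id(calibrator.mirna_id):
        raise ValueError(
            f"mismatched miRNA ids: {sample.mirna_id!r} vs {calibrator.mirna_id!r}"
        )
    return float(2.0 ** -(sample.delta_ct - calibrator.delta_ct))


def differential_call(fold_change: float, mirna_id: str = "") -> DifferentialCall:
    """Symmetric >= 2-fold rule: differential when fold >= 2 or fold <= 0.5."""
    if not fold_change > 0:
        raise ValueError("fold change must be > 0")
    return DifferentialCall(
        mirna_id=harmonize_mirna_id(mirna_id),
        fold_change=fold_change,
        is_differential=bool(fold_change >= 2.0 or fold_change <= 0.5),
    )


def call_differentials(
    ct_table: pd.DataFrame,
    calibrator_condition: str = "proliferation",
    sample_condition: str = "differentiation",
) -> pd.DataFrame:
    """Fold changes and differential calls for every miRNA of a Ct table.

    The calibrator condition (proliferating cells by default) sets the
    reference state; replicate Ct values within a condition are averaged
    before the fold change is computed.
    """
    required = {"mirna_id", "condition", "ct_target", "ct_reference"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    table = ct_table.copy()
    table["mirna_id"] = table["mirna_id"].map(harmonize_mirna_id)
    table["delta_ct"] = table["ct_target"] - table["ct_reference"]
    rows = []
    for mirna, grp in table.groupby("mirna_id", sort=True):
        cal = grp.loc[grp["condition"] == calibrator_condition, "delta_ct"]
        smp = grp.loc[grp["condition"] == sample_condition, "delta_ct"]
        if cal.empty or smp.empty:
            continue
        fold = float(2.0 ** -(smp.mean() - cal.mean()))
        call = differential_call(fold, mirna)
        rows.append(
            {
                "mirna_id": mirna,
                "fold_change": fold,
                "is_differential": call.is_differential,
            }
        )
    return pd.DataFrame(rows, columns=["mirna_id", "fold_change", "is_differential"])


def knockdown_efficiency(treated: CtRecord, control: CtRecord) -> float:
    """Percent inhibition of the target miRNA, clipped below at 0."""
    fold = ddct_fold_change(treated, control)
    return max(0.0, 100.0 * (1.0 - fold))


def _hit_members(hit_id: str) -> list[str]:
    # slash-joined family entries ("hsa-mir-106a/hsa-mir-17") share one row
    return [harmonize_mirna_id(m) for m in hit_id.split("/") if m.strip()]


def intersect_hits(
    hit_ids: Iterable[str],
    differential_calls: pd.DataFrame,
    profiled_ids: Iterable[str],
) -> dict[str, float]:
    """Overlap bookkeeping between functional hits and expression calls.

    Identifiers are case-harmonized; a slash-joined family hit counts once
    and matches when any member matches.  Returns the counts of
    differential-only, functional-only and doubly positive miRNAs plus the
    profiling coverage fraction of the hit list.
    """
    hits = [str(h) for h in hit_ids]
    differential = {
        harmonize_mirna_id(m)
        for m, d in zip(
            differential_calls["mirna_id"], differential_calls["is_differential"]
        )
        if bool(d)
    }
    profiled = {harmonize_mirna_id(m) for m in profiled_ids}
    both = sum(
        1 for h in hits if any(m in differential for m in _hit_members(h))
    )
    covered = sum(1 for h in hits if any(m in profiled for m in _hit_members(h)))
    all_members = {m for h in hits for m in _hit_members(h)}
    return {
        "n_hits": len(hits),
        "n_differential": len(differential),
        "both": both,
        "functional_only": len(hits) - both,
        "differential_only": len(differential - all_members),
        "coverage": covered / len(hits) if hits else 0.0,
    }


def tap_tar_enrichment(
    target_values: Sequence[float], control_values: Sequence[float]
) -> float:
    """Mean per-replicate pulldown ratio of test miRNA over control miRNA."""
    t = np.asarray(target_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("need at least one replicate per group")
    if t.size != c.size:
        raise ValueError("per-replicate ratios require paired replicate vectors")
    if np.any(c == 0):
        raise ValueError("control pulldown value of zero; ratio undefined")
    return float(np.mean(t / c))


def reporter_ratio(
    renilla: float,
    firefly: float,
    control_renilla: float,
    control_firefly: float,
) -> float:
    """Dual-luciferase readout as percent of control (control set to 100)."""
    if firefly <= 0 or control_firefly <= 0:
        raise ValueError("firefly values must be > 0")
    if control_renilla <= 0:
        raise ValueError("control renilla must be > 0")
    return 100.0 * (renilla / firefly) / (control_renilla / control_firefly)
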