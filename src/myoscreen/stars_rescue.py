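"""Suppressor-rescue (co-knockdown) calling.

Each gene is tested by several siRNAs co-transfected with a miRNA LNA
inhibitor.  A siRNA rescues when the LNA + siRNA wells show a
significantly higher fusion index than the LNA + control-siRNA wells
(one-sided Mann-Whitney); a gene is a target hit when at least
``min_rescuing`` (default 2) of its siRNAs rescue.  A two-stage variant
screens 2 siRNAs per gene first and 2 more for genes with at least one
stage-1 rescuer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .screen_analysis import mann_whitney

__all__ = [
    "CONTROL_ID",
    "RescueTestResult",
    "RescueCall",
    "relative_fusion_index",
    "rescue_test",
    "call_target",
    "two_stage_screen",
    "specificity_matrix",
    "rescue_dominance",
]

CONTROL_ID = "control"

WELL_COLUMNS = ("lna_id", "sirna_id", "gene", "replicate", "fusion_index")


class RescueTestResult(NamedTuple):
    rescued: bool
    p_value: float
    evaluable: bool


@dataclass
class RescueCall:
    """Per-gene outcome of the rescue screen under one LNA."""

    gene: str
    lna_id: str
    n_sirnas_tested: int
    n_rescuing: int
    is_hit: bool
    per_sirna: dict[str, RescueTestResult] = field(default_factory=dict)
    rel_fusion_indices: dict[str, float] = field(default_factory=dict)


def _check_wells(wells: pd.DataFrame) -> None:
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"well table is missing columns {missing}")


def relative_fusion_index(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize fusion indices to the control-LNA + control-siRNA mean.

    Adds a ``rel_fusion_index`` column; reference wells normalize to 1 on
    average.
    """
    _check_wells(wells)
    ref_mask = (wells["lna_id"] == CONTROL_ID) & (wells["sirna_id"] == CONTROL_ID)
    if not ref_mask.any():
        raise ValueError(
            "no reference wells (control LNA + control siRNA) in the table"
        )
    ref_mean = wells.loc[ref_mask, "fusion_index"].mean()
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ValueError("reference fusion-index mean is zero; cannot normalize")
    out = wells.copy()
    out["rel_fusion_index"] = out["fusion_index"] / ref_mean
    return out


def rescue_test(
    sirna_values: Sequence[float],
    lna_control_values: Sequence[float],
    alpha: float = 0.05,
) -> RescueTestResult:
    """Test one siRNA for phenotypic rescue.

    Rescue means the LNA + siRNA wells have significantly greater fusion
    index than LNA + control-siRNA wells (one-sided Mann-Whitney,
    ``p < alpha``).  Groups with fewer than 3 replicates are unevaluable.
    """
    a = np.asarray(sirna_values, dtype=float)
    b = np.asarray(lna_control_values, dtype=float)
    if a.size < 3 or b.size < 3:
        return RescueTestResult(rescued=False, p_value=float("nan"), evaluable=False)
    p = mann_whitney(a, b, "greater")
    return RescueTestResult(rescued=bool(p < alpha), p_value=p, evaluable=True)


def call_target(
    gene: str,
    sirna_results: Mapping[str, RescueTestResult],
    min_rescuing: int = 2,
    lna_id: str = "",
) -> RescueCall:
    """Call a gene from its per-siRNA rescue results (hit when >= min_rescuing)."""
    if not sirna_results:
        raise ValueError(f"no siRNAs tested for gene {gene!r}")
    n_rescuing = sum(1 for r in sirna_results.values() if r.evaluable and r.rescued)
    return RescueCall(
        gene=gene,
        lna_id=lna_id,
        n_sirnas_tested=len(sirna_results),
        n_rescuing=n_rescuing,
        is_hit=n_rescuing >= min_rescuing,
        per_sirna=dict(sirna_results),
    )


def _sirna_results(
    wells: pd.DataFrame,
    lna_id: str,
    gene: str,
    baseline: np.ndarray,
    alpha: float,
    metric: str,
) -> dict[str, RescueTestResult]:
    sub = wells[
        (wells["lna_id"] == lna_id)
        & (wells["gene"] == gene)
        & (wells["sirna_id"] != CONTROL_ID)
    ]
    results = {}
    for sirna_id, grp in sub.groupby("sirna_id", sort=True):
        results[str(sirna_id)] = rescue_test(grp[metric].to_numpy(), baseline, alpha)
    return results


def _baseline(wells: pd.DataFrame, lna_id: str, metric: str) -> np.ndarray:
    base = wells[(wells["lna_id"] == lna_id) & (wells["sirna_id"] == CONTROL_ID)]
    if base.empty:
        raise ValueError(f"no LNA + control-siRNA wells for LNA {lna_id!r}")
    return base[metric].to_numpy()


def two_stage_screen(
    stage1: pd.DataFrame,
    stage2: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_rescuing: int = 2,
    combine_stages: bool = True,
    metric: str = "fusion_index",
) -> list[RescueCall]:
    """Run the two-stage rescue screen over every (LNA, gene) pair.

    Stage 1 (2 siRNAs/gene) passes a gene when at least one siRNA rescues;
    only passers are evaluated with the stage-2 siRNAs.  The final call
    applies the >= ``min_rescuing`` rule over all siRNAs of both stages
    (or over stage 2 alone when ``combine_stages`` is False).  Stage-2
    data for genes that failed stage 1 are ignored with a warning.
    """
    _check_wells(stage1)
    calls: list[RescueCall] = []
    lnas = sorted(
        set(stage1.loc[stage1["lna_id"] != CONTROL_ID, "lna_id"].unique())
    )
    for lna in lnas:
        baseline1 = _baseline(stage1, lna, metric)
        genes = sorted(
            set(
                stage1.loc[
                    (stage1["lna_id"] == lna) & (stage1["gene"] != CONTROL_ID),
                    "gene",
                ].unique()
            )
        )
        passed: dict[str, dict[str, RescueTestResult]] = {}
        for gene in genes:
            res1 = _sirna_results(stage1, lna, gene, baseline1, alpha, metric)
            if any(r.evaluable and r.rescued for r in res1.values()):
                passed[gene] = res1
            else:
                calls.append(call_target(gene, res1, min_rescuing, lna))
        if stage2 is not None and not stage2.empty:
            _check_wells(stage2)
            baseline2 = (
                _baseline(stage2, lna, metric)
                if ((stage2["lna_id"] == lna) & (stage2["sirna_id"] == CONTROL_ID)).any()
                else baseline1
            )
            stage2_genes = set(
                stage2.loc[
                    (stage2["lna_id"] == lna) & (stage2["gene"] != CONTROL_ID),
                    "gene",
                ].unique()
            )
            orphan = stage2_genes - set(passed)
            if orphan:
                warnings.warn(
                    f"stage-2 data for genes that failed stage 1 ignored: "
                    f"{sorted(orphan)}",
                    stacklevel=2,
                )
            for gene in sorted(set(passed) & stage2_genes):
                res2 = _sirna_results(stage2, lna, gene, baseline2, alpha, metric)
                merged = dict(res2) if not combine_stages else {**passed[gene], **res2}
                calls.append(call_target(gene, merged, min_rescuing, lna))
                del passed[gene]
        for gene, res1 in passed.items():
            calls.append(call_target(gene, res1, min_rescuing, lna))
    calls.sort(key=lambda c: (c.lna_id, c.gene))
    return calls


def specificity_matrix(
    wells: pd.DataFrame,
    alpha: float = 0.05,
    metric: str = "fusion_index",
) -> pd.DataFrame:
    """Cross-LNA rescue matrix: entry (LNA m, gene g) is True when gene g's
    pooled siRNA wells rescue the phenotype under LNA m."""
    _check_wells(wells)
    lnas = sorted(set(wells.loc[wells["lna_id"] != CONTROL_ID, "lna_id"].unique()))
    genes = sorted(set(wells.loc[wells["gene"] != CONTROL_ID, "gene"].unique()))
    matrix = pd.DataFrame(False, index=lnas, columns=genes, dtype=bool)
    for lna in lnas:
        baseline = _baseline(wells, lna, metric)
        for gene in genes:
            pool = wells[
                (wells["lna_id"] == lna)
                & (wells["gene"] == gene)
                & (wells["sirna_id"] != CONTROL_ID)
            ][metric].to_numpy()
            if pool.size < 3:
                continue
            p = mann_whitney(pool, baseline, "greater")
            matrix.loc[lna, gene] = bool(p < alpha)
    matrix.index.name = "lna_id"
    matrix.columns.name = "gene"
    return matrix


def rescue_dominance(
    matrix: pd.DataFrame, on_target: Mapping[str, str]
) -> float:
    """Fraction of on-target rescues minus fraction of off-target rescues.

    ``on_target`` maps each gene to the LNA whose miRNA it is a putative
    target of.  Returns 0 for an all-False (null) matrix.
    """
    on_hits = on_total = off_hits = off_total = 0
    for lna in matrix.index:
        for gene in matrix.columns:
            if on_target.get(gene) == lna:
                on_total += 1
                on_hits += bool(matrix.loc[lna, gene])
            else:
                off_total += 1
                off_hits += bool(matrix.loc[lna, gene])
    on_frac = on_hits / on_total if on_total else 0.0
    off_frac = off_hits / off_total if off_total else 0.0
    return on_frac - off_frac
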