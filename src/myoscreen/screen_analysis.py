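"""Two-tier hit calling for a plate-based loss-of-function screen.

Well metrics are normalized to the mock-transfected control of their plate,
primary candidates are selected by a mean-minus-k-SD rule on the pooled
negative controls, and candidates are confirmed with exact Mann-Whitney
tests against the pooled control wells before being sorted into phenotype
categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from math import comb, erf, sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "LayoutEntry",
    "PlateLayout",
    "AnalysisParams",
    "PhenotypeCategory",
    "CATEGORY_ORDER",
    "HitCall",
    "subtract_death_background",
    "normalize_to_mock",
    "primary_select",
    "mann_whitney",
    "significance_code",
    "secondary_confirm",
    "classify_phenotype",
    "summarize_screen",
]

#: Closed vocabulary of well roles.
ROLES = frozenset({"sample", "neg_ctrl", "mock", "pos_ctrl", "death_ctrl"})

#: Metric columns normalized / adjusted by default.
METRIC_COLUMNS = ("pct_myotubes", "cell_count")


@dataclass(frozen=True)
class LayoutEntry:
    reagent_id: str
    role: str
    concentration: float = 100.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"unknown role {self.role!r}; expected one of {sorted(ROLES)}"
            )


@dataclass(frozen=True)
class PlateLayout:
    """Mapping from well id to the reagent it received and its control role."""

    entries: Mapping[str, LayoutEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("layout has no wells")
        if not any(e.role == "mock" for e in self.entries.values()):
            raise ValueError("layout must contain at least one mock well")

    def wells_with_role(self, *roles: str) -> list[str]:
        for r in roles:
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r}")
        return [w for w, e in self.entries.items() if e.role in roles]

    def role_of(self, well_id: str) -> str:
        return self.entries[well_id].role

    def reagent_of(self, well_id: str) -> str:
        return self.entries[well_id].reagent_id


@dataclass(frozen=True)
class AnalysisParams:
    """Tuning knobs of the two-tier hit caller.

    k_sd
        Number of negative-control standard deviations defining the primary
        selection threshold (default 2).
    alpha
        Mann-Whitney significance level for confirmation (default 0.05).
    direction
        ``"lower"`` selects only reduced-differentiation candidates;
        ``"both"`` additionally selects candidates above mean + k_sd * SD.
    low_count_threshold_pct
        Relative cell count (percent of control) below which an inhibited
        hit is classed as "low cell count".
    viability_exclusion_pct
        Optional residual-viability floor; candidates whose relative cell
        count falls below it are excluded from confirmation.
    """

    k_sd: float = 2.0
    alpha: float = 0.05
    direction: str = "lower"
    low_count_threshold_pct: float = 70.0
    viability_exclusion_pct: float | None = None
    min_nuclei_per_myotube: int = 3

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.direction not in ("lower", "both"):
            raise ValueError("direction must be 'lower' or 'both'")


class PhenotypeCategory(str, Enum):
    INHIBITED = "inhibited"
    INHIBITED_LOW_COUNT = "inhibited_low_count"
    INHIBITED_HIGH_COUNT = "inhibited_high_count"
    ENHANCED = "enhanced"
    HIGH_COUNT = "high_count"
    NOT_HIT = "not_hit"


#: Report ordering of categories (hit categories first).
CATEGORY_ORDER: tuple[PhenotypeCategory, ...] = (
    PhenotypeCategory.INHIBITED,
    PhenotypeCategory.INHIBITED_LOW_COUNT,
    PhenotypeCategory.INHIBITED_HIGH_COUNT,
    PhenotypeCategory.ENHANCED,
    PhenotypeCategory.HIGH_COUNT,
    PhenotypeCategory.NOT_HIT,
)


@dataclass
class HitCall:
    reagent_id: str
    rel_pct_myotubes: float
    rel_cell_count: float
    p_diff: float = float("nan")
    p_count: float = float("nan")
    sig_diff: str = "ns"
    sig_count: str = "ns"
    direction: str = "low"
    evaluable: bool = True
    confirmed: bool = False
    category: PhenotypeCategory = PhenotypeCategory.NOT_HIT
    pct_replicates: tuple[float, ...] = field(default_factory=tuple)
    count_replicates: tuple[float, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# plate-level adjustments


def _require_columns(table: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing required columns {missing}")


def subtract_death_background(
    plate: pd.DataFrame,
    layout: PlateLayout,
    metrics: Sequence[str] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """Subtract the mean of the transfection-death control wells, floored at 0."""
    _require_columns(plate, ["well_id", *metrics])
    death_wells = set(layout.wells_with_role("death_ctrl"))
    if not death_wells:
        raise ValueError("no death_ctrl wells in layout; cannot subtract background")
    out = plate.copy()
    mask = out["well_id"].isin(death_wells)
    for m in metrics:
        background = out.loc[mask, m].mean()
        out[m] = (out[m] - background).clip(lower=0)
    return out


def normalize_to_mock(
    plate: pd.DataFrame,
    layout: PlateLayout,
    metrics: Sequence[str] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """Express each metric as percent of the same-plate mock-well mean.

    Adds ``rel_<metric>`` columns.  When a ``plate_id`` column is present,
    normalization is per plate; otherwise the whole table is one plate.
    """
    _require_columns(plate, ["well_id", *metrics])
    mock_wells = set(layout.wells_with_role("mock"))
    out = plate.copy()
    groups = out.groupby("plate_id", sort=False) if "plate_id" in out.columns else [
        (None, out)
    ]
    for _, sub in groups:
        mask = sub["well_id"].isin(mock_wells)
        if not mask.any():
            raise ValueError("plate has no mock wells; cannot normalize")
        for m in metrics:
            mock_mean = sub.loc[mask, m].mean()
            if not np.isfinite(mock_mean) or mock_mean <= 0:
                raise ValueError(f"mock mean for {m!r} is zero; plate failed")
            out.loc[sub.index, f"rel_{m}"] = 100.0 * sub[m] / mock_mean
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Null distribution of the Mann-Whitney U statistic (no ties).

    Returns counts[u] = number of rank assignments with U == u, via the
    standard recurrence c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).
    """
    max_u = n1 * n2
    # table[i][j] is the count vector for sample sizes (i, j)
    prev = [np.zeros(max_u + 1, dtype=np.int64) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        prev[j][0] = 1  # n1 == 0
    for i in range(1, n1 + 1):
        cur = [np.zeros(max_u + 1, dtype=np.int64) for _ in range(n2 + 1)]
        cur[0][0] = 1
        for j in range(1, n2 + 1):
            shifted = np.zeros(max_u + 1, dtype=np.int64)
            shifted[j:] = prev[j][: max_u + 1 - j]
            cur[j] = shifted + cur[j - 1]
        prev = cur
    return tuple(int(c) for c in prev[n2])


def _exact_p(u: float, n1: int, n2: int, alternative: str) -> float:
    counts = _u_null_counts(n1, n2)
    total = comb(n1 + n2, n1)
    u_int = int(round(u))
    if alternative == "less":
        return sum(counts[: u_int + 1]) / total
    if alternative == "greater":
        return sum(counts[u_int:]) / total
    mid = n1 * n2 / 2.0
    dev = abs(u_int - mid)
    tail = sum(c for v, c in enumerate(counts) if abs(v - mid) >= dev - 1e-9)
    return tail / total


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
) -> float:
    """Mann-Whitney rank-sum p-value for sample ``a`` versus sample ``b``.

    Exact by full enumeration of rank assignments when ``len(a) + len(b)
    <= 12`` and the pooled data contain no ties; otherwise a normal
    approximation with mid-rank tie correction and continuity correction.
    ``alternative="less"`` tests whether ``a`` tends to be smaller than
    ``b``.  The returned p lies in (0, 1].
    """
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError("alternative must be 'two_sided', 'less' or 'greater'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    # mid-ranks
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    i = 0
    pos = 1
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (pos + pos + (j - i)) / 2.0
        pos += j - i + 1
        i = j + 1
    has_ties = np.unique(pooled).size < pooled.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= 12 and not has_ties:
        return min(1.0, max(_exact_p(u, n1, n2, alternative), 1.0 / comb(n1 + n2, n1)))

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return 1.0  # all observations identical: no evidence
    sd = sqrt(var_u)

    def phi(z: float) -> float:
        return 0.5 * (1.0 + erf(z / sqrt(2.0)))

    if alternative == "less":
        p = phi((u - mean_u + 0.5) / sd)
    elif alternative == "greater":
        p = 1.0 - phi((u - mean_u - 0.5) / sd)
    else:
        z = (abs(u - mean_u) - 0.5) / sd
        p = 2.0 * (1.0 - phi(max(z, 0.0)))
    return min(1.0, max(p, np.finfo(float).tiny))


def significance_code(p: float) -> str:
    """Footnote-style code: ``***`` p<0.005, ``**`` p<0.01, ``*`` p<0.05."""
    if not np.isfinite(p):
        return "ns"
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# primary selection


def _neg_pool_wells(layout: PlateLayout) -> list[str]:
    # Negative reference pool: mutant-LNA wells plus mock wells.
    return layout.wells_with_role("neg_ctrl", "mock")


def primary_select(
    records: pd.DataFrame,
    layout: PlateLayout,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[pd.DataFrame, float]:
    """Select primary candidates by the mean - k_sd * SD rule.

    ``records`` is a normalized well table (``rel_pct_myotubes`` present).
    The threshold is computed over the pooled negative-control wells; a
    reagent whose mean relative myotube percentage is <= threshold is a
    candidate (boundary values are selected).  With ``direction="both"``
    reagents at or above the symmetric upper threshold are selected too.

    Returns ``(candidates, threshold)`` where ``candidates`` has columns
    ``reagent_id``, ``mean_rel_pct_myotubes`` and ``direction``.
    """
    _require_columns(records, ["well_id", "rel_pct_myotubes"])
    neg_wells = set(_neg_pool_wells(layout))
    neg = records.loc[records["well_id"].isin(neg_wells), "rel_pct_myotubes"]
    if neg.size < 2:
        raise ValueError("need >= 2 negative-control wells to estimate the SD")
    mean, sd = float(neg.mean()), float(neg.std(ddof=1))
    threshold = mean - params.k_sd * sd
    upper = mean + params.k_sd * sd

    sample_wells = set(layout.wells_with_role("sample"))
    samples = records[records["well_id"].isin(sample_wells)].copy()
    samples["reagent_id"] = samples["well_id"].map(
        lambda w: layout.reagent_of(w)
    )
    per_reagent = (
        samples.groupby("reagent_id", sort=False)["rel_pct_myotubes"]
        .mean()
        .rename("mean_rel_pct_myotubes")
        .reset_index()
    )
    low = per_reagent["mean_rel_pct_myotubes"] <= threshold
    rows = per_reagent[low].assign(direction="low")
    if params.direction == "both":
        high = per_reagent["mean_rel_pct_myotubes"] >= upper
        rows = pd.concat(
            [rows, per_reagent[high & ~low].assign(direction="high")],
            ignore_index=True,
        )
    candidates = rows.reset_index(drop=True)
    candidates.attrs["threshold_low"] = threshold
    candidates.attrs["threshold_high"] = upper
    return candidates, threshold


# ---------------------------------------------------------------------------
# secondary confirmation and classification


def classify_phenotype(
    hit: HitCall, params: AnalysisParams = AnalysisParams()
) -> PhenotypeCategory:
    """Assign exactly one phenotype category to an evaluable hit call.

    An inhibition-direction hit (significantly reduced differentiation,
    mean below control) is split on relative cell count: below the
    low-count threshold with a significant count change -> low count;
    above 100 with a significant count change -> high count; otherwise the
    plain inhibited class.  Non-inhibited reagents may be called enhanced
    (significantly above control) or high-count only.
    """
    if not hit.evaluable:
        return PhenotypeCategory.NOT_HIT
    alpha = params.alpha
    diff_sig = np.isfinite(hit.p_diff) and hit.p_diff < alpha
    count_sig = np.isfinite(hit.p_count) and hit.p_count < alpha
    inhibited = diff_sig and hit.rel_pct_myotubes < 100 and hit.direction == "low"
    if inhibited:
        if hit.rel_cell_count < params.low_count_threshold_pct and count_sig:
            return PhenotypeCategory.INHIBITED_LOW_COUNT
        if hit.rel_cell_count > 100 and count_sig:
            return PhenotypeCategory.INHIBITED_HIGH_COUNT
        return PhenotypeCategory.INHIBITED
    if diff_sig and hit.rel_pct_myotubes > 100:
        return PhenotypeCategory.ENHANCED
    if count_sig and hit.rel_cell_count > 100:
        return PhenotypeCategory.HIGH_COUNT
    return PhenotypeCategory.NOT_HIT


def secondary_confirm(
    candidates: pd.DataFrame,
    records: pd.DataFrame,
    layout: PlateLayout,
    params: AnalysisParams = AnalysisParams(),
) -> list[HitCall]:
    """Confirm primary candidates against the pooled negative controls.

    For each candidate the replicate vectors of relative myotube
    percentage and relative cell count are compared with the pooled
    negative-control wells by Mann-Whitney (one-sided in the candidate's
    direction for differentiation, two-sided for cell count).  Candidates
    with fewer than 3 replicates are flagged unevaluable rather than
    dropped.
    """
    _require_columns(records, ["well_id", "rel_pct_myotubes", "rel_cell_count"])
    neg_wells = set(_neg_pool_wells(layout))
    neg = records[records["well_id"].isin(neg_wells)]
    if neg.empty:
        raise ValueError("no negative-control wells available for confirmation")
    ctrl_pct = neg["rel_pct_myotubes"].to_numpy()
    ctrl_cnt = neg["rel_cell_count"].to_numpy()

    by_reagent: dict[str, list[str]] = {}
    for w in layout.wells_with_role("sample"):
        by_reagent.setdefault(layout.reagent_of(w), []).append(w)

    calls: list[HitCall] = []
    for row in candidates.itertuples(index=False):
        reagent = row.reagent_id
        direction = getattr(row, "direction", "low")
        wells = set(by_reagent.get(reagent, []))
        sub = records[records["well_id"].isin(wells)]
        vals_pct = sub["rel_pct_myotubes"].to_numpy()
        vals_cnt = sub["rel_cell_count"].to_numpy()
        call = HitCall(
            reagent_id=reagent,
            rel_pct_myotubes=float(np.mean(vals_pct)) if vals_pct.size else float("nan"),
            rel_cell_count=float(np.mean(vals_cnt)) if vals_cnt.size else float("nan"),
            direction=direction,
            pct_replicates=tuple(vals_pct),
            count_replicates=tuple(vals_cnt),
        )
        if vals_pct.size < 3:
            call.evaluable = False
            calls.append(call)
            continue
        if (
            params.viability_exclusion_pct is not None
            and call.rel_cell_count < params.viability_exclusion_pct
        ):
            call.evaluable = False
            calls.append(call)
            continue
        side = "less" if direction == "low" else "greater"
        call.p_diff = mann_whitney(vals_pct, ctrl_pct, side)
        call.p_count = mann_whitney(vals_cnt, ctrl_cnt, "two_sided")
        call.sig_diff = significance_code(call.p_diff)
        call.sig_count = significance_code(call.p_count)
        deviates = (
            call.rel_pct_myotubes < np.mean(ctrl_pct)
            if direction == "low"
            else call.rel_pct_myotubes > np.mean(ctrl_pct)
        )
        call.confirmed = bool(call.p_diff < params.alpha and deviates)
        call.category = classify_phenotype(call, params)
        if direction == "high" and call.category == PhenotypeCategory.NOT_HIT:
            # an up-direction candidate may still be a pure high-count hit
            call.confirmed = False
        calls.append(call)
    return calls


def summarize_screen(
    hit_calls: Sequence[HitCall],
    normalized: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Build the final hit table and an optional plate-well series export.

    The hit table contains one row per confirmed (or otherwise categorized)
    hit, grouped in the fixed category order.  The series table lists every
    well in plate order with its relative myotube percentage, suitable for
    a plate-well series plot.
    """
    rows = []
    order = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    hits = [
        h
        for h in hit_calls
        if h.evaluable and h.category != PhenotypeCategory.NOT_HIT
    ]
    for h in sorted(hits, key=lambda h: (order[h.category], h.reagent_id)):
        rows.append(
            {
                "category": h.category.value,
                "reagent_id": h.reagent_id,
                "rel_pct_myotubes": h.rel_pct_myotubes,
                "sig_diff": h.sig_diff,
                "rel_cell_count": h.rel_cell_count,
                "sig_count": h.sig_count,
                "p_diff": h.p_diff,
                "p_count": h.p_count,
            }
        )
    hit_table = pd.DataFrame(
        rows,
        columns=[
            "category",
            "reagent_id",
            "rel_pct_myotubes",
            "sig_diff",
            "rel_cell_count",
            "sig_count",
            "p_diff",
            "p_count",
        ],
    )
    series = None
    if normalized is not None:
        series = normalized.copy()
        series["series_index"] = np.arange(len(series))
        keep = ["series_index", "well_id", "rel_pct_myotubes"]
        if "plate_id" in series.columns:
            keep.insert(1, "plate_id")
        series = series[keep]
    return hit_table, series
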