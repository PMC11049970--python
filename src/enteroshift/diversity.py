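"""Shannon diversity, group comparisons, and representative-taxon selection.

The representative-taxon procedure builds the ordered genus set used for
composition (pie-chart) profiles: starting from a candidate pool of genera
with at least a 2-fold significant response somewhere in the series, it
cycles through a fixed order of profiles and, at each step, takes the
not-yet-selected pool genus most abundant in the current profile.  Five
rounds over ten profiles give fifty taxa; the dominant genus of each control
profile may then be dropped post hoc to improve resolution, and a
"normalizing sector" N pads every profile's selected-taxa total up to the
maximum so profiles are directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import shannon as _skbio_shannon

from .abundance import AbundanceMatrix, ReadCountTable
from .differential import DifferentialResult

__all__ = [
    "DiversityResult",
    "PieSelection",
    "GroupComparison",
    "shannon_index",
    "diversity_table",
    "compare_groups",
    "candidate_pool",
    "select_representatives",
    "remove_dominants",
    "normalizing_sector",
]


@dataclass
class DiversityResult:
    sample_id: str
    shannon: float
    n_taxa: int


@dataclass
class GroupComparison:
    test: str  # "t" | "rank-sum"
    statistic: float
    p: float
    normal_a: bool
    normal_b: bool
    degenerate: bool = False


@dataclass
class PieSelection:
    """Ordered representative taxa with per-profile totals."""

    taxa: list[str]
    profile_order: list[str]
    percent: pd.DataFrame  # profiles x selected taxa
    removed_dominants: list[str] = field(default_factory=list)

    @property
    def totals(self) -> pd.Series:
        return self.percent[self.taxa].sum(axis=1)


class ShortSelectionError(RuntimeError):
    """Candidate pool exhausted before the requested selection size."""

    def __init__(self, partial: "PieSelection"):
        super().__init__(
            f"pool exhausted after {len(partial.taxa)} taxa"
        )
        self.partial = partial


def shannon_index(abundances: Sequence[float] | pd.Series, base: float = 2) -> float:
    """Shannon diversity H' = -sum p log_base p over detected taxa."""
    x = np.asarray(abundances, dtype=float)
    if x.sum() <= 0:
        raise ValueError("all-zero abundance row")
    if (x < 0).any():
        raise ValueError("negative abundances")
    return float(_skbio_shannon(x[x > 0], base=base))


def diversity_table(table: ReadCountTable, base: float = 2) -> list[DiversityResult]:
    """Per-sample H' and identified-taxon count (>= 1 read) from raw counts."""
    out = []
    for sid in table.sample_ids:
        row = table.counts.loc[sid].to_numpy()
        out.append(DiversityResult(sid, shannon_index(row, base=base), int((row > 0).sum())))
    return out


def compare_groups(values_a: Sequence[float], values_b: Sequence[float], alpha_normality: float = 0.05) -> GroupComparison:
    """Two-group comparison with a normality gate.

    Shapiro-Wilk is applied to each group; if both pass at
    ``alpha_normality`` a Student's t-test is used, otherwise the Wilcoxon
    rank-sum test.  Constant groups are flagged degenerate and compared by
    rank-sum (normality is undefined for them).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    degenerate = a.std() == 0 or b.std() == 0
    if degenerate:
        stat, p = stats.ranksums(a, b)
        return GroupComparison("rank-sum", float(stat), float(p), False, False, True)
    na = stats.shapiro(a).pvalue > alpha_normality
    nb = stats.shapiro(b).pvalue > alpha_normality
    if na and nb:
        stat, p = stats.ttest_ind(a, b)
        return GroupComparison("t", float(stat), float(p), na, nb)
    stat, p = stats.ranksums(a, b)
    return GroupComparison("rank-sum", float(stat), float(p), na, nb)


def candidate_pool(
    results_by_timepoint: Mapping[str, Iterable[DifferentialResult]],
    min_fold: float = 2.0,
    alpha: float = 0.05,
) -> set[str]:
    """Genera with a significant >= ``min_fold`` response at >= 1 time point.

    A genus must pass the inclusion filters (i.e. be assessed at all) in
    every compared time point, and show mean FCR >= min_fold or
    <= 1/min_fold with p < alpha somewhere in the series.
    """
    by_tp = {tp: {r.genus: r for r in results} for tp, results in results_by_timepoint.items()}
    if not by_tp:
        return set()
    everywhere = set.intersection(*(set(d) for d in by_tp.values()))
    pool = set()
    for genus in everywhere:
        for d in by_tp.values():
            r = d[genus]
            if r.degenerate or r.p is None:
                continue
            if r.p < alpha and (r.mean_fcr >= min_fold or r.mean_fcr <= 1.0 / min_fold):
                pool.add(genus)
                break
    return pool


def select_representatives(
    pool: Iterable[str],
    ab: AbundanceMatrix,
    profile_order: Sequence[str],
    rounds: int = 5,
) -> PieSelection:
    """Stepwise greedy selection cycling through the profile order.

    For ``rounds`` full cycles, the most abundant not-yet-selected pool genus
    of the current profile is appended; ties break lexicographically, so the
    result is deterministic.  Raises :class:`ShortSelectionError` carrying
    the partial result if the pool runs out early.
    """
    profiles = list(profile_order)
    pool = sorted(set(pool))
    pct = ab.percent.loc[profiles].fillna(0.0)
    missing = [g for g in pool if g not in pct.columns]
    if missing:
        raise KeyError(f"pool genera absent from abundance matrix: {missing[:5]}")
    selected: list[str] = []
    remaining = set(pool)
    for _ in range(rounds):
        for profile in profiles:
            if not remaining:
                partial = PieSelection(selected, profiles, pct)
                raise ShortSelectionError(partial)
            row = pct.loc[profile]
            best = min(remaining, key=lambda g: (-row[g], g))
            selected.append(best)
            remaining.discard(best)
    return PieSelection(selected, profiles, pct)


def remove_dominants(
    sel: PieSelection,
    control_profiles: Sequence[str],
    n_per_profile: int = 1,
) -> PieSelection:
    """Drop the top-abundance selected genus of each control profile.

    If two control profiles share their dominant genus it is removed once.
    Totals are recomputed over the surviving taxa.
    """
    if not sel.taxa:
        raise ValueError("empty selection")
    removed: list[str] = []
    for profile in control_profiles:
        row = sel.percent.loc[profile, [t for t in sel.taxa if t not in removed]]
        for genus in row.sort_values(ascending=False).index[:n_per_profile]:
            if genus not in removed:
                removed.append(genus)
    kept = [t for t in sel.taxa if t not in removed]
    return PieSelection(kept, sel.profile_order, sel.percent, sel.removed_dominants + removed)


def normalizing_sector(sel: PieSelection) -> pd.Series:
    """Per-profile padding N = max total - total, equalizing padded totals."""
    totals = sel.totals
    return totals.max() - totals
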