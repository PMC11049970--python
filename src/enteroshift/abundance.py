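"""Count-table ingestion, marker-panel construction and percentage matrices.

Genus-level read counts (the tabular output of a 16S read classifier) are
held as a samples x genera integer matrix with per-sample metadata.  The
marker panel is the union of genera reaching a relative-abundance threshold
in at least one sample; percentages are computed within the panel, optionally
after adding a single pseudocount read to zero cells (the convention used for
fold-change ratios, where division by zero must be avoided) and optionally
after masking hand-flagged outlier cells, whose reads are removed from both
numerator and denominator before renormalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReadCountTable",
    "MarkerPanel",
    "AbundanceMatrix",
    "read_counts",
    "select_marker_panel",
    "mask_outliers",
    "percentages",
    "phylum_summary",
    "flag_outlier_candidates",
    "read_phylum_map",
]

#: metadata columns every sample must carry
METADATA_COLUMNS = ("rat_id", "group", "time_point", "environment", "is_control")


class ParseError(ValueError):
    """Malformed count or metadata input."""


class DegenerateSampleError(ValueError):
    """A sample lost all of its reads (zero total, or fully masked)."""


@dataclass
class ReadCountTable:
    """Samples x genera integer read counts plus per-sample metadata.

    ``counts`` is indexed by sample id with one column per genus;
    ``metadata`` is indexed by sample id and carries at least
    ``rat_id, group, time_point, environment, is_control`` and optionally
    ``known_enterotype``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ParseError("duplicate sample ids in count table")
        if (self.counts.values < 0).any():
            raise ParseError("negative read counts")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            vals = self.counts.values
            if not np.allclose(vals, np.round(vals)):
                raise ParseError("non-integer read counts")
            self.counts = self.counts.astype(np.int64)
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise ParseError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ParseError(f"metadata missing required column {col!r}")
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered genus list passing an abundance threshold in >= 1 sample."""

    genus_ids: tuple[str, ...]
    threshold_percent: float
    source_sets: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genus_ids)

    def __iter__(self):
        return iter(self.genus_ids)


@dataclass
class AbundanceMatrix:
    """Renormalized percentage matrix over a marker panel.

    Masked cells are NaN and excluded from both numerator and denominator;
    each row sums to 100 over its unmasked entries.
    """

    percent: pd.DataFrame
    mask: frozenset = field(default_factory=frozenset)
    pseudocount: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.percent.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.percent.columns)

    def row(self, sample_id: str) -> pd.Series:
        return self.percent.loc[sample_id]

    def subset(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(sample_ids)
        return AbundanceMatrix(self.percent.loc[ids], self.mask, self.pseudocount)


def _normalize_name(name: str) -> str:
    return str(name).strip()


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    return df


def read_counts(count_path, metadata_path) -> ReadCountTable:
    """Read a wide (sample x genus) or long (sample, genus, reads) count table.

    The dialect is detected from the header: a three-column table whose
    header contains ``genus`` and ``reads`` (case-insensitive) is treated as
    long and aggregated by summation over duplicate (sample, genus) rows.
    The first column always holds the sample id.
    """
    raw = _read_table(count_path)
    header = [str(c).strip().lower() for c in raw.columns]
    if len(raw.columns) == 3 and "genus" in header and "reads" in header:
        raw.columns = header
        sample_col = [c for c in header if c not in ("genus", "reads")][0]
        long = raw.rename(columns={sample_col: "sample"})
        long["sample"] = long["sample"].map(_normalize_name)
        long["genus"] = long["genus"].map(_normalize_name)
        counts = (
            long.pivot_table(index="sample", columns="genus", values="reads", aggfunc="sum", fill_value=0)
        )
        counts.columns.name = None
        counts.index.name = None
    else:
        counts = raw.set_index(raw.columns[0])
        counts.index = counts.index.map(_normalize_name)
        counts.index.name = None
        counts.columns = [_normalize_name(c) for c in counts.columns]
    for col in counts.columns:
        if not pd.api.types.is_numeric_dtype(counts[col]):
            raise ParseError(f"non-numeric counts in column {col!r}")
    counts = counts.fillna(0)

    meta = _read_table(metadata_path)
    meta = meta.set_index(meta.columns[0])
    meta.index = meta.index.map(_normalize_name)
    meta.index.name = None
    if "is_control" in meta.columns:
        meta["is_control"] = meta["is_control"].astype(str).str.lower().isin(("1", "true", "yes"))
    extra = counts.index.difference(meta.index)
    if len(extra):
        raise ParseError(f"count samples missing from metadata: {sorted(extra)[:5]}")
    return ReadCountTable(counts, meta)


def select_marker_panel(table: ReadCountTable, threshold_percent: float = 0.01) -> MarkerPanel:
    """Union of genera reaching ``threshold_percent`` in at least one sample.

    Each sequenced sample is treated as one dataset.  Order is deterministic:
    descending maximal per-sample abundance, ties broken lexicographically.
    """
    if threshold_percent <= 0:
        raise ValueError("threshold_percent must be positive")
    if table.counts.empty or int(table.counts.values.sum()) == 0:
        raise ValueError("cannot build a marker panel from an empty count table")
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0]
        raise DegenerateSampleError(f"samples with zero reads: {list(empty)[:5]}")
    pct = table.counts.div(totals, axis=0) * 100.0
    max_pct = pct.max(axis=0)
    keep = max_pct[max_pct >= threshold_percent]
    order = sorted(keep.index, key=lambda g: (-keep[g], g))
    return MarkerPanel(tuple(order), threshold_percent, tuple(table.sample_ids))


def percentages(
    table: ReadCountTable,
    panel: MarkerPanel | Iterable[str],
    pseudocount: int = 0,
) -> AbundanceMatrix:
    """Percentage matrix restricted to the panel.

    With ``pseudocount=1`` a single read is added to every zero-count panel
    cell before normalization (the fold-change-ratio convention); with 0 the
    raw proportions are used (the clustering convention).
    """
    genera = list(panel.genus_ids if isinstance(panel, MarkerPanel) else panel)
    if not genera:
        raise ValueError("empty panel")
    if pseudocount not in (0, 1):
        raise ValueError("pseudocount must be 0 or 1")
    sub = table.counts.reindex(columns=genera, fill_value=0).astype(float)
    if pseudocount:
        sub = sub.where(sub > 0, other=float(pseudocount))
    totals = sub.sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0]
        raise DegenerateSampleError(f"samples with zero panel reads: {list(empty)[:5]}")
    return AbundanceMatrix(sub.div(totals, axis=0) * 100.0, frozenset(), pseudocount)


def mask_outliers(
    table: ReadCountTable,
    mask_list: Iterable[tuple[str, str]],
    panel: MarkerPanel | Iterable[str] | None = None,
    pseudocount: int = 0,
) -> AbundanceMatrix:
    """Percentages with hand-flagged (sample, genus) cells ignored.

    The masked reads drop out of the denominator, so the remaining genera are
    renormalized to 100% — ratios among unmasked genera are preserved exactly.
    """
    genera = list(panel.genus_ids if isinstance(panel, MarkerPanel) else panel) if panel is not None else table.genus_ids
    mask = frozenset((str(s), str(g)) for s, g in mask_list)
    for s, g in mask:
        if s not in table.counts.index or g not in table.counts.columns:
            raise KeyError(f"mask refers to unknown cell ({s!r}, {g!r})")
    sub = table.counts.reindex(columns=genera, fill_value=0).astype(float)
    if pseudocount:
        sub = sub.where(sub > 0, other=1.0)
    for s, g in mask:
        if g in sub.columns:
            sub.loc[s, g] = np.nan
    totals = sub.sum(axis=1)  # skips NaN
    if (totals == 0).any():
        bad = totals.index[totals == 0]
        raise DegenerateSampleError(f"all reads masked for samples: {list(bad)[:5]}")
    return AbundanceMatrix(sub.div(totals, axis=0) * 100.0, mask, pseudocount)


def phylum_summary(ab: AbundanceMatrix, phylum_of: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample phylum percentages with the Bacteroidota/Bacillota ratio.

    Unmapped genera are pooled as ``other``.  The B/F ratio (Bacteroidota over
    Bacillota, the phylum-level enterotype discriminator) is +inf when a
    sample carries no Bacillota reads.
    """
    groups = {g: phylum_of.get(g, "other") for g in ab.genus_ids}
    filled = ab.percent.fillna(0.0)
    summary = filled.T.groupby(pd.Series(groups)).sum().T
    bact = summary.get("Bacteroidota", pd.Series(0.0, index=summary.index))
    firm = summary.get("Bacillota", pd.Series(0.0, index=summary.index))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(firm > 0, bact / firm, math.inf)
    summary = summary.copy()
    summary["B/F"] = ratio
    return summary


def flag_outlier_candidates(ab: AbundanceMatrix, factor: float = 10.0, quantile: float = 0.95) -> list[tuple[str, str]]:
    """Advisory detector: cells whose percentage exceeds ``factor`` times the
    genus's cross-sample ``quantile``.  Never masks anything by itself."""
    flags: list[tuple[str, str]] = []
    pct = ab.percent
    ref = pct.quantile(quantile, axis=0)
    for g in pct.columns:
        bound = factor * ref[g]
        if bound <= 0:
            continue
        hot = pct.index[pct[g] > bound]
        flags.extend((s, g) for s in hot)
    return sorted(flags)


def read_phylum_map(path) -> dict[str, str]:
    """TSV/CSV with two columns genus, phylum."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ParseError("phylum map needs two columns (genus, phylum)")
    return {
        _normalize_name(g): _normalize_name(p)
        for g, p in zip(df.iloc[:, 0], df.iloc[:, 1])
    }
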