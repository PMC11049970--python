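"""Paired fold-change-ratio (FCR) statistics for probiotic response.

Each experimental sample is paired with its control (the same rat before
treatment, or the untreated parallel culture in vitro), the per-genus FCR is
the pseudocounted experimental percentage over the control percentage, and a
one-sample Z-test against FCR = 1 summarizes each genus within a group of
pairs.  Inclusion filters drop pairs whose relevant percentage (experimental
for increases, control for decreases) is below a floor, and genera with
fewer than a minimum number of qualifying pairs.  Cross-context concordance
labels (similar / opposite) and chance-expected Venn overlaps support the
in-vivo vs in-vitro comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceMatrix, MarkerPanel

__all__ = [
    "PairSet",
    "DifferentialResult",
    "OverlapSummary",
    "build_pairs",
    "compute_fcr",
    "apply_inclusion_filter",
    "z_statistic",
    "differential_table",
    "volcano_table",
    "concordance",
    "overlap_summary",
]

#: percentage floor for a pair to qualify (percentage points)
DEFAULT_MIN_PERCENT = 0.01
#: minimum qualifying pairs for a genus to be assessed
DEFAULT_MIN_PAIRS = 3

TIME_ORDER = ("0h", "24h", "48h", "72h", "14d")


class PairingError(ValueError):
    """Metadata cannot support the requested pairing scheme."""


@dataclass
class PairSet:
    """Control/experimental sample pairs sharing a group label.

    A control may legitimately appear in several pairs: recovery time points
    are each compared against the same pre-treatment sample.
    """

    pairs: list[tuple[str, str]]
    group_label: str
    enterotype: str = ""

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DifferentialResult:
    genus: str
    group_label: str
    n: int
    mean_fcr: float
    sd_fcr: float
    z: float | None
    p: float | None
    direction: str  # "stimulated" | "suppressed"
    degenerate: bool = False


@dataclass
class OverlapSummary:
    size_a: int
    size_b: int
    universe: int
    observed: int
    expected: float
    p_enrichment: float  # hypergeometric upper tail, advisory


def _doses_by_time(group: str) -> dict[str, int]:
    """Doses received by each sampling time under the feeding protocol:
    one dose at 0 h for every rat, plus doses at 24 h and 48 h for the
    triple-dose ("multiple") group."""
    if group == "single":
        return {"24h": 1, "48h": 1, "72h": 1, "14d": 1}
    if group == "multiple":
        return {"24h": 1, "48h": 2, "72h": 3, "14d": 3}
    raise PairingError(f"unknown dosing group {group!r}")


def build_pairs(
    metadata: pd.DataFrame,
    scheme: str,
    exclude: Iterable[tuple[str, str]] = (),
) -> list[PairSet]:
    """Construct control/experimental pairs under one of three schemes.

    dosing    — fecal samples taken while dosing is still informative are
                paired to the rat's 0 h control, grouped by enterotype and
                number of doses received (label ``dose-N/<time>``);
    recovery  — post-treatment fecal time points paired to the same 0 h
                control (label ``recovery/<time>``);
    in_vitro  — cultures grown with probiotic paired to the parallel culture
                without it, matched on origin rat/sample and duration.

    ``exclude`` lists (control, experimental) pairs to drop, mirroring the
    hand-excluded suspect culture pairs.
    """
    excl = set(tuple(e) for e in exclude)
    out: list[PairSet] = []
    if scheme in ("dosing", "recovery"):
        fecal = metadata[metadata["environment"] == "fecal"]
        controls: dict[str, str] = {}
        for sid, row in fecal[fecal["is_control"]].iterrows():
            controls[row["rat_id"]] = sid
        treated = fecal[~fecal["is_control"]]
        missing = set(treated["rat_id"]) - set(controls)
        if missing:
            raise PairingError(f"rats lacking a 0h control: {sorted(missing)[:5]}")
        buckets: dict[tuple[str, str], list[tuple[str, str]]] = {}
        for sid, row in treated.iterrows():
            doses = _doses_by_time(row["group"])
            tp = row["time_point"]
            if tp not in doses:
                raise PairingError(f"unknown time point {tp!r} for sample {sid!r}")
            n_doses = doses[tp]
            # a time point is "recovery" once no further dose preceded it
            last_dose_tp = {1: "24h", 2: "48h", 3: "72h"}[n_doses]
            is_recovery = tp != last_dose_tp
            if scheme == "recovery" and not is_recovery:
                continue
            label = (
                f"recovery/{tp}" if scheme == "recovery" else f"dose-{n_doses}/{tp}"
            )
            ent = str(row.get("known_enterotype", "") or "")
            pair = (controls[row["rat_id"]], sid)
            if pair in excl:
                continue
            buckets.setdefault((ent, label), []).append(pair)
        for (ent, label), pairs in sorted(buckets.items()):
            out.append(PairSet(sorted(pairs), label, ent))
    elif scheme == "in_vitro":
        cultured = metadata[metadata["environment"].isin(["GMM", "GMM_probiotic"])]
        key_of = lambda row: (row["rat_id"], row["time_point"])
        gm: dict[tuple, str] = {}
        pr: dict[tuple, str] = {}
        for sid, row in cultured.iterrows():
            (gm if row["environment"] == "GMM" else pr)[key_of(row)] = sid
        buckets = {}
        for key in sorted(set(gm) & set(pr)):
            pair = (gm[key], pr[key])
            if pair in excl:
                continue
            rat, tp = key
            ent = str(metadata.loc[gm[key]].get("known_enterotype", "") or "")
            buckets.setdefault((ent, f"Pr-vs-GM/{tp}"), []).append(pair)
        for (ent, label), pairs in sorted(buckets.items()):
            out.append(PairSet(sorted(pairs), label, ent))
    else:
        raise ValueError(f"unknown pairing scheme {scheme!r}")
    return out


def compute_fcr(
    ab_pseudo: AbundanceMatrix,
    pairs: PairSet,
    panel: MarkerPanel | Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-genus, per-pair fold change ratios.

    ``ab_pseudo`` must be built with pseudocount 1 so every percentage is
    strictly positive.  Returns a long table with columns genus, control,
    experimental, control_pct, experimental_pct, fcr.
    """
    if ab_pseudo.pseudocount != 1:
        raise ValueError("compute_fcr requires a pseudocounted abundance matrix")
    genera = list(panel) if panel is not None else ab_pseudo.genus_ids
    rows = []
    for ctrl, expt in pairs.pairs:
        for sid in (ctrl, expt):
            if sid not in ab_pseudo.percent.index:
                raise KeyError(f"pair member {sid!r} missing from abundance matrix")
        c = ab_pseudo.percent.loc[ctrl, genera]
        e = ab_pseudo.percent.loc[expt, genera]
        for g in genera:
            rows.append((g, ctrl, expt, float(c[g]), float(e[g]), float(e[g] / c[g])))
    return pd.DataFrame(
        rows, columns=["genus", "control", "experimental", "control_pct", "experimental_pct", "fcr"]
    )


def apply_inclusion_filter(
    records: pd.DataFrame,
    min_percent: float = DEFAULT_MIN_PERCENT,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> dict[str, pd.DataFrame]:
    """Keep, per genus, the qualifying pairs; drop genera with too few.

    A pair qualifies when the percentage on the side that matters is at or
    above ``min_percent``: the experimental side for an increased genus
    (fcr >= 1), the control side for a suppressed one.
    """
    qualifies = np.where(
        records["fcr"] >= 1.0,
        records["experimental_pct"] >= min_percent,
        records["control_pct"] >= min_percent,
    )
    kept = records[qualifies]
    out: dict[str, pd.DataFrame] = {}
    for genus, grp in kept.groupby("genus", sort=True):
        if len(grp) >= min_pairs:
            out[genus] = grp.reset_index(drop=True)
    return out


def z_statistic(
    fcrs: Sequence[float],
    genus: str = "",
    group_label: str = "",
    use_sem: bool = True,
) -> DifferentialResult:
    """One-sample Z-test of the mean FCR against the null FCR = 1.

    ``z = (mean - 1) / (sd / sqrt(n))`` by default (``use_sem=False`` divides
    by sd alone).  The p-value is the upper tail of the standard normal at
    |z|, evaluated with the complementary error function so that it stays
    finite and positive for very large z (no underflow at z = 10 or beyond).
    Direction follows the sign of mean - 1.
    """
    x = np.asarray(list(fcrs), dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least three qualifying pairs")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    direction = "stimulated" if mean >= 1.0 else "suppressed"
    if sd == 0.0:
        if mean == 1.0:  # exactly null: z = 0 is well defined despite sd = 0
            return DifferentialResult(genus, group_label, n, mean, sd, 0.0, 0.5, direction)
        return DifferentialResult(genus, group_label, n, mean, sd, None, None, direction, degenerate=True)
    denom = sd / math.sqrt(n) if use_sem else sd
    z = (mean - 1.0) / denom
    # norm.sf uses erfc internally: stable far into the tail
    p = float(stats.norm.sf(abs(z)))
    p = max(p, np.nextafter(0.0, 1.0))
    return DifferentialResult(genus, group_label, n, mean, sd, z, p, direction)


def differential_table(
    ab_pseudo: AbundanceMatrix,
    pairs: PairSet,
    panel: MarkerPanel | Iterable[str] | None = None,
    min_percent: float = DEFAULT_MIN_PERCENT,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    use_sem: bool = True,
) -> list[DifferentialResult]:
    """FCR -> filter -> Z pipeline for one pair set."""
    records = compute_fcr(ab_pseudo, pairs, panel)
    kept = apply_inclusion_filter(records, min_percent, min_pairs)
    return [
        z_statistic(grp["fcr"], genus, pairs.group_label, use_sem=use_sem)
        for genus, grp in kept.items()
    ]


def volcano_table(results: Iterable[DifferentialResult]) -> pd.DataFrame:
    """Export rows for a volcano plot: log2 mean FCR vs -log10 p with
    significance tiers at p <= 0.001 ("strong") and p < 0.05 ("significant")."""
    results = list(results)
    if not results:
        raise ValueError("no results to tabulate")
    rows = []
    for r in results:
        if r.degenerate or r.p is None:
            tier = "degenerate"
            nlp = np.nan
        elif r.p <= 0.001:
            tier, nlp = "strong", -math.log10(r.p)
        elif r.p < 0.05:
            tier, nlp = "significant", -math.log10(r.p)
        else:
            tier, nlp = "ns", -math.log10(r.p)
        rows.append(
            (r.genus, r.group_label, r.n, r.mean_fcr, math.log2(r.mean_fcr), r.z, r.p, nlp, r.direction, tier)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genus", "group", "n", "mean_fcr", "log2_mean_fcr", "z", "p",
            "neg_log10_p", "direction", "tier",
        ],
    ).sort_values(["group", "p"], na_position="last").reset_index(drop=True)


def concordance(
    results_a: Iterable[DifferentialResult],
    results_b: Iterable[DifferentialResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label genera as similar / opposite / none across two contexts.

    similar: significant (p < alpha) in both contexts with the same
    direction; opposite: significant in both with discordant directions;
    none otherwise (including genera assessed in only one context).
    """
    a = {r.genus: r for r in results_a}
    b = {r.genus: r for r in results_b}
    rows = []
    for genus in sorted(set(a) | set(b)):
        ra, rb = a.get(genus), b.get(genus)
        label = "none"
        if ra and rb and not ra.degenerate and not rb.degenerate:
            if ra.p < alpha and rb.p < alpha:
                label = "similar" if ra.direction == rb.direction else "opposite"
        rows.append(
            (
                genus,
                ra.direction if ra else None, ra.p if ra else None,
                rb.direction if rb else None, rb.p if rb else None,
                label,
            )
        )
    return pd.DataFrame(
        rows, columns=["genus", "direction_a", "p_a", "direction_b", "p_b", "label"]
    )


def overlap_summary(set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]) -> OverlapSummary:
    """Observed vs chance-expected intersection of two responder sets.

    expected = |A| * |B| / |U|, the count expected if membership in B were a
    random draw from the universe; the hypergeometric upper-tail p is
    attached as an advisory enrichment measure.
    """
    U = set(universe)
    if not U:
        raise ValueError("empty universe")
    A, B = set(set_a) & U, set(set_b) & U
    if set(set_a) - U or set(set_b) - U:
        raise ValueError("sets must be subsets of the universe")
    observed = len(A & B)
    expected = len(A) * len(B) / len(U)
    p = float(stats.hypergeom.sf(observed - 1, len(U), len(A), len(B)))
    return OverlapSummary(len(A), len(B), len(U), observed, expected, p)
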