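"""Enterotype clustering and stability assessment.

The enterotyping procedure follows the classical recipe for compositional
gut-community data: root Jensen-Shannon divergence between renormalized
genus profiles as the sample distance, partition-around-medoids (PAM) as the
clusterer, a medoid-based Calinski-Harabasz index to scan the cluster
number, and per-sample silhouette scores to judge how firmly each sample
sits in its cluster.  Stability of the two-enterotype call is probed by
re-clustering every pooled combination of the time-point sample sets and
counting, for each sample, in how many combinations it lands in each
(harmonized) enterotype with silhouette above a threshold; the majority of
those "true" assignments is the final call.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from sklearn.metrics import silhouette_samples

from .abundance import AbundanceMatrix

__all__ = [
    "DistanceMatrix",
    "Partition",
    "ClusterScan",
    "SilhouetteGrid",
    "EnterotypeCall",
    "jsd_distance",
    "pam",
    "ch_scan",
    "silhouette",
    "enumerate_pooled_sets",
    "stability_grid",
    "call_enterotype",
    "pcoa_coordinates",
]

logger = logging.getLogger(__name__)

#: default zero-replacement on proportions before taking logs
DEFAULT_PSEUDO = 1e-10
#: silhouette threshold above which a clustering result counts as a vote
DEFAULT_VOTE_THRESHOLD = 0.1


@dataclass
class DistanceMatrix:
    """Symmetric root-JSD distances with their computation conventions."""

    sample_ids: list[str]
    d: np.ndarray
    pseudo: float = DEFAULT_PSEUDO
    log_base: str = "e"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def index_of(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class Partition:
    """PAM result: cluster labels and the medoid sample of each cluster."""

    labels: dict[str, int]
    medoids: dict[int, str]
    k: int

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster]


@dataclass
class ClusterScan:
    ch_index: dict[int, float]
    optimal_k: int


@dataclass
class SilhouetteGrid:
    """(combination x sample) silhouette scores and harmonized labels.

    ``S`` and ``cluster_of`` are DataFrames indexed by combination name; a
    NaN / None cell means the sample was absent from that combination.
    """

    combinations: list[tuple[str, ...]]
    S: pd.DataFrame
    cluster_of: pd.DataFrame
    threshold: float = DEFAULT_VOTE_THRESHOLD

    def to_heatmap_frame(self) -> pd.DataFrame:
        """S x 100 rounded to integers, the display convention."""
        return (self.S * 100).round(0)


@dataclass
class EnterotypeCall:
    sample_id: str
    votes: dict[str, int]
    decision: str  # enterotype label or "unstable"
    threshold: float = DEFAULT_VOTE_THRESHOLD


def _proportions(ab: AbundanceMatrix, pseudo: float) -> np.ndarray:
    p = ab.percent.fillna(0.0).to_numpy(dtype=float) / 100.0
    if (p < 0).any():
        raise ValueError("negative abundances")
    p = np.where(p <= 0, pseudo, p)
    return p / p.sum(axis=1, keepdims=True)


def jsd_distance(ab: AbundanceMatrix, pseudo: float = DEFAULT_PSEUDO, log_base: str = "e") -> DistanceMatrix:
    """Pairwise root Jensen-Shannon divergence between abundance rows.

    Zeros are replaced by ``pseudo`` and rows renormalized before taking
    logs.  ``d(i, j) = sqrt(KL(p_i || m)/2 + KL(p_j || m)/2)`` with ``m`` the
    midpoint; bounded by sqrt(log 2) in the chosen base.
    """
    if log_base not in ("e", "2"):
        raise ValueError("log_base must be 'e' or '2'")
    p = _proportions(ab, pseudo)
    n = p.shape[0]
    d = np.zeros((n, n))
    scale = 1.0 if log_base == "e" else 1.0 / np.log(2.0)
    chunk = 64  # row blocks keep the (chunk, n, genera) temporaries small
    for i0 in range(0, n, chunk):
        block = p[i0:i0 + chunk]
        m = 0.5 * (block[:, None, :] + p[None, :, :])
        div = 0.5 * rel_entr(block[:, None, :], m).sum(axis=-1)
        div += 0.5 * rel_entr(np.broadcast_to(p[None, :, :], m.shape), m).sum(axis=-1)
        d[i0:i0 + chunk] = div
    d = 0.5 * (d + d.T) * scale
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ab.sample_ids), np.sqrt(np.clip(d, 0.0, None)), pseudo, log_base)


def _pam_cost(d: np.ndarray, medoids: Sequence[int]) -> float:
    return float(d[:, list(medoids)].min(axis=1).sum())


def pam(dm: DistanceMatrix, k: int, seed: int = 0) -> Partition:
    """Partition around medoids with the classical BUILD + SWAP search.

    BUILD is deterministic (greedy gain); SWAP repeatedly applies the
    single-medoid swap with the largest cost reduction, so the final total
    distance to medoids is a local optimum under single swaps.  ``seed``
    only permutes the tie-break order among equally good swaps.
    """
    n = len(dm)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    d = dm.d
    rng = np.random.default_rng(seed)
    # BUILD: first medoid minimizes total distance, then greedy additions
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(current - d[:, c], 0.0).sum() if c not in medoids else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    # SWAP: steepest descent over (medoid, candidate) exchanges
    cost = _pam_cost(d, medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        order = rng.permutation(n)
        for c in order:
            if c in medoids:
                continue
            for mi, m in enumerate(medoids):
                trial = medoids.copy()
                trial[mi] = int(c)
                delta = cost - _pam_cost(d, trial)
                if delta > best[0] + 1e-12:
                    best = (delta, mi, int(c))
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost -= best[0]
            improved = True
    medoids = sorted(medoids)
    assign = d[:, medoids].argmin(axis=1)
    # keep duplicates of a medoid with the medoid's own cluster
    labels = {dm.sample_ids[i]: int(assign[i]) for i in range(n)}
    for ci, m in enumerate(medoids):
        labels[dm.sample_ids[m]] = ci
    part = Partition(labels, {ci: dm.sample_ids[m] for ci, m in enumerate(medoids)}, k)
    for ci in range(k):
        if not part.members(ci):  # pragma: no cover - BUILD makes this unreachable
            raise RuntimeError("empty cluster in PAM result")
    return part


def ch_scan(dm: DistanceMatrix, k_range: Iterable[int] = range(2, 6), seed: int = 0) -> ClusterScan:
    """Calinski-Harabasz scan over PAM partitions, adapted to distances.

    Dispersions are medoid-based: between-cluster B sums n_c * d(medoid_c,
    global medoid)^2, within-cluster W sums squared distances of samples to
    their own medoid; CH(k) = (B/(k-1)) / (W/(n-k)).
    """
    n = len(dm)
    if n < 4:
        raise ValueError("need at least 4 samples for a cluster-number scan")
    ks = [k for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    d = dm.d
    global_medoid = int(np.argmin(d.sum(axis=0)))
    ch: dict[int, float] = {}
    for k in ks:
        part = pam(dm, k, seed=seed)
        idx = {s: i for i, s in enumerate(dm.sample_ids)}
        B = 0.0
        W = 0.0
        for ci, m in part.medoids.items():
            members = part.members(ci)
            B += len(members) * d[idx[m], global_medoid] ** 2
            W += sum(d[idx[s], idx[m]] ** 2 for s in members)
        if W <= 0:
            ch[k] = np.inf
        else:
            ch[k] = (B / (k - 1)) / (W / (n - k))
    optimal = max(ch, key=lambda k: (ch[k], -k))
    return ClusterScan(ch, optimal)


def silhouette(dm: DistanceMatrix, part: Partition) -> dict[str, float]:
    """Per-sample silhouette scores on the precomputed distance matrix.

    ``S(i) = (b - a) / max(a, b)`` with a the mean intra-cluster distance
    and b the smallest mean distance to another cluster; singletons score 0.
    """
    labels = np.array([part.labels[s] for s in dm.sample_ids])
    if len(set(labels)) < 2:
        raise ValueError("silhouette needs at least two clusters")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = silhouette_samples(dm.d, labels, metric="precomputed")
    return {s: float(v) for s, v in zip(dm.sample_ids, scores)}


def enumerate_pooled_sets(timepoint_sets: Sequence[str]) -> list[tuple[str, ...]]:
    """All unordered combinations of >= 2 of the time-point sets.

    Five sets give 10 pairs, 10 triplets, 5 quartets and 1 quintet, in
    deterministic order (by size, then by position of the members).
    """
    sets = list(timepoint_sets)
    if len(sets) < 2:
        raise ValueError("need at least two time-point sets to pool")
    out: list[tuple[str, ...]] = []
    for size in range(2, len(sets) + 1):
        out.extend(itertools.combinations(sets, size))
    return out


def combination_name(combo: tuple[str, ...]) -> str:
    return "_".join(combo)


def _harmonize(
    part: Partition,
    reference_labels: Mapping[str, str],
) -> dict[str, str]:
    """Map raw PAM cluster ids to enterotype names by majority overlap of the
    member reference (control) samples; invariant to raw-id relabeling."""
    names = sorted(set(reference_labels.values()))
    overlap = {
        ci: {nm: sum(1 for s in part.members(ci) if reference_labels.get(s) == nm) for nm in names}
        for ci in part.medoids
    }
    mapping: dict[int, str] = {}
    taken: set[str] = set()
    # greedy: strongest overlap first, deterministic tie-break by (cluster, name)
    cells = sorted(
        ((overlap[ci][nm], ci, nm) for ci in overlap for nm in names),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for _, ci, nm in cells:
        if ci in mapping or nm in taken:
            continue
        mapping[ci] = nm
        taken.add(nm)
    leftover = [nm for nm in names if nm not in taken]
    for ci in overlap:
        if ci not in mapping:
            mapping[ci] = leftover.pop(0) if leftover else f"C{ci}"
    return {s: mapping[c] for s, c in part.labels.items()}


def stability_grid(
    ab_by_timepoint: Mapping[str, AbundanceMatrix],
    reference_labels: Mapping[str, str],
    pseudo: float = DEFAULT_PSEUDO,
    log_base: str = "e",
    threshold: float = DEFAULT_VOTE_THRESHOLD,
    seed: int = 0,
) -> SilhouetteGrid:
    """Silhouette scores and harmonized enterotype labels for every pooled
    combination of the time-point sample sets.

    ``reference_labels`` maps the control samples to their enterotype as
    called on the control-only clustering; each combination is re-clustered
    from scratch (JSD then PAM with k=2) and its two clusters renamed by
    majority overlap of member controls with the reference.
    """
    set_names = list(ab_by_timepoint)
    combos = enumerate_pooled_sets(set_names)
    all_samples: list[str] = []
    for name in set_names:
        for s in ab_by_timepoint[name].sample_ids:
            if s not in all_samples:
                all_samples.append(s)
    rows = [combination_name(c) for c in combos]
    S = pd.DataFrame(np.nan, index=rows, columns=all_samples)
    C = pd.DataFrame(None, index=rows, columns=all_samples, dtype=object)
    for combo in combos:
        frames = [ab_by_timepoint[name].percent for name in combo]
        merged = pd.concat(frames, axis=0)
        merged = merged[~merged.index.duplicated(keep="first")]
        if len(merged) < 4:
            logger.warning("skipping combination %s with < 4 samples", combo)
            continue
        ab = AbundanceMatrix(merged)
        dm = jsd_distance(ab, pseudo=pseudo, log_base=log_base)
        part = pam(dm, 2, seed=seed)
        sil = silhouette(dm, part)
        harmonized = _harmonize(part, reference_labels)
        row = combination_name(combo)
        for s in merged.index:
            S.loc[row, s] = sil[s]
            C.loc[row, s] = harmonized[s]
    return SilhouetteGrid(combos, S, C, threshold)


def call_enterotype(grid: SilhouetteGrid, sample_id: str, threshold: float | None = None) -> EnterotypeCall:
    """Majority vote over combinations where the sample's silhouette exceeds
    the threshold; ties and zero votes are conservatively ``unstable``."""
    if sample_id not in grid.S.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    thr = grid.threshold if threshold is None else threshold
    votes: dict[str, int] = {}
    for row in grid.S.index:
        s = grid.S.loc[row, sample_id]
        if pd.isna(s) or s <= thr:
            continue
        label = grid.cluster_of.loc[row, sample_id]
        votes[label] = votes.get(label, 0) + 1
    if not votes:
        return EnterotypeCall(sample_id, votes, "unstable", thr)
    top = max(votes.values())
    winners = [lab for lab, v in votes.items() if v == top]
    decision = winners[0] if len(winners) == 1 else "unstable"
    return EnterotypeCall(sample_id, votes, decision, thr)


def pcoa_coordinates(dm: DistanceMatrix, n_axes: int = 2) -> pd.DataFrame:
    """Classical metric multidimensional scaling (PCoA) of the distances.

    Axes are ordered by eigenvalue; negative eigenvalues are truncated (with
    the library's warning suppressed into a log message).
    """
    if n_axes >= len(dm):
        raise ValueError("n_axes must be smaller than the number of samples")
    from skbio.stats.ordination import pcoa as _pcoa
    from skbio import DistanceMatrix as _SkbioDM

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = _pcoa(_SkbioDM(dm.d, ids=dm.sample_ids), number_of_dimensions=n_axes)
    for w in caught:
        logger.info("pcoa: %s", w.message)
    coords = res.samples.iloc[:, :n_axes]
    coords.columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return coords
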