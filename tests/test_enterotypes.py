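import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from enteroshift.abundance import AbundanceMatrix, percentages, select_marker_panel
from enteroshift.enterotypes import (
    DistanceMatrix,
    call_enterotype,
    ch_scan,
    enumerate_pooled_sets,
    jsd_distance,
    pam,
    pcoa_coordinates,
    silhouette,
    stability_grid,
    SilhouetteGrid,
)
from enteroshift.synthetic import (
    EffectModel,
    SyntheticDesign,
    shift_effects,
    simulate_cohort,
)


def ab_from_rows(rows: dict[str, list[float]]) -> AbundanceMatrix:
    df = pd.DataFrame(rows).T
    df = df.div(df.sum(axis=1), axis=0) * 100
    df.columns = [f"g{i}" for i in range(df.shape[1])]
    return AbundanceMatrix(df)


# ------------------------------------------------------------------------ JSD

def test_jsd_identical_rows_zero():
    ab = ab_from_rows({"a": [0.3, 0.7], "b": [0.3, 0.7]})
    assert jsd_distance(ab).d[0, 1] == pytest.approx(0.0, abs=1e-6)


def test_jsd_disjoint_supports_maximal():
    ab = ab_from_rows({"a": [1.0, 0.0], "b": [0.0, 1.0]})
    assert jsd_distance(ab).d[0, 1] == pytest.approx(math.sqrt(math.log(2)), abs=1e-4)


def test_jsd_matches_term_by_term_oracle():
    p, q = [0.5, 0.5], [0.25, 0.75]
    m = [0.5 * (a + b) for a, b in zip(p, q)]
    expected = math.sqrt(
        0.5 * sum(a * math.log(a / c) for a, c in zip(p, m))
        + 0.5 * sum(b * math.log(b / c) for b, c in zip(q, m))
    )
    ab = ab_from_rows({"a": p, "b": q})
    assert jsd_distance(ab).d[0, 1] == pytest.approx(expected, abs=1e-9)


def test_jsd_agrees_with_scipy_on_random_compositions():
    rng = np.random.default_rng(5)
    x = rng.dirichlet(np.ones(30), size=12)
    ab = ab_from_rows({f"s{i}": list(x[i]) for i in range(12)})
    d = jsd_distance(ab)
    for i in range(12):
        for j in range(i + 1, 12):
            assert d.d[i, j] == pytest.approx(jensenshannon(x[i], x[j]), abs=1e-5)


def test_jsd_metric_axioms_on_random_compositions():
    """Identity, symmetry and the triangle inequality over 200 draws."""
    rng = np.random.default_rng(17)
    x = rng.dirichlet(np.ones(25) * 0.5, size=200)
    ab = ab_from_rows({f"s{i}": list(x[i]) for i in range(200)})
    d = jsd_distance(ab).d
    assert np.allclose(np.diag(d), 0)
    assert np.allclose(d, d.T)
    assert d.max() <= math.sqrt(math.log(2)) + 1e-9
    trip = rng.integers(0, 200, size=(400, 3))
    for i, j, k in trip:
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_jsd_rejects_negative():
    df = pd.DataFrame([[-1.0, 101.0]], index=["a"], columns=["g0", "g1"])
    with pytest.raises(ValueError):
        jsd_distance(AbundanceMatrix(df))


# ------------------------------------------------------------------------ PAM

def dm_from_points(points: dict[str, complex]) -> DistanceMatrix:
    ids = list(points)
    n = len(ids)
    d = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            d[i, j] = abs(points[a] - points[b])
    return DistanceMatrix(ids, d)


def brute_force_pam_cost(d: np.ndarray, k: int) -> float:
    n = d.shape[0]
    return min(
        d[:, list(meds)].min(axis=1).sum()
        for meds in itertools.combinations(range(n), k)
    )


def test_pam_separates_tight_pairs():
    dm = dm_from_points({"a": 0, "b": 0.1, "c": 10, "d": 10.1})
    part = pam(dm, 2)
    assert part.labels["a"] == part.labels["b"]
    assert part.labels["c"] == part.labels["d"]
    assert part.labels["a"] != part.labels["c"]


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("k", [2, 3])
def test_pam_matches_brute_force_small_n(seed, k):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(7, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    dm = DistanceMatrix([f"s{i}" for i in range(7)], d)
    part = pam(dm, k, seed=seed)
    idx = {s: i for i, s in enumerate(dm.sample_ids)}
    cost = sum(d[idx[s], idx[part.medoids[c]]] for s, c in part.labels.items())
    assert cost == pytest.approx(brute_force_pam_cost(d, k), abs=1e-9)


def test_pam_duplicates_share_cluster():
    dm = dm_from_points({"a": 0, "a2": 0, "b": 5, "b2": 5})
    part = pam(dm, 2)
    assert part.labels["a"] == part.labels["a2"]
    assert part.labels["b"] == part.labels["b2"]


def test_pam_invalid_k():
    dm = dm_from_points({"a": 0, "b": 1, "c": 2})
    with pytest.raises(ValueError):
        pam(dm, 3)


def test_pam_invariant_to_row_permutation():
    rng = np.random.default_rng(3)
    pts = {f"s{i}": complex(rng.normal(), rng.normal()) for i in range(9)}
    dm = dm_from_points(pts)
    part = pam(dm, 2)
    shuffled = dict(reversed(list(pts.items())))
    part2 = pam(dm_from_points(shuffled), 2)
    groups1 = frozenset(frozenset(part.members(c)) for c in part.medoids)
    groups2 = frozenset(frozenset(part2.members(c)) for c in part2.medoids)
    assert groups1 == groups2


# -------------------------------------------------------------------- CH scan

def test_ch_scan_two_planted_clusters():
    rng = np.random.default_rng(0)
    pts = {f"a{i}": complex(rng.normal(scale=1.0), rng.normal(scale=1.0)) for i in range(8)}
    pts |= {f"b{i}": complex(8 + rng.normal(scale=1.0), rng.normal(scale=1.0)) for i in range(8)}
    scan = ch_scan(dm_from_points(pts), range(2, 5))
    assert scan.optimal_k == 2
    assert all(v > 0 for v in scan.ch_index.values())


def test_ch_scan_three_replicated_groups():
    # three equidistant points, each replicated 5x: W = 0 exactly at k = 3
    centers = [complex(0, 0), complex(10, 0), complex(5, 10 * math.sqrt(3) / 2)]
    pts = {f"c{c}_{i}": centers[c] for c in range(3) for i in range(5)}
    scan = ch_scan(dm_from_points(pts), range(2, 6))
    assert scan.optimal_k == 3


def test_ch_scan_too_few_samples():
    with pytest.raises(ValueError):
        ch_scan(dm_from_points({"a": 0, "b": 1, "c": 2}), range(2, 3))


# ----------------------------------------------------------------- silhouette

def test_silhouette_separable_pairs_high():
    dm = dm_from_points({"a": 0, "b": 0.01, "c": 10, "d": 10.01})
    part = pam(dm, 2)
    assert all(v > 0.9 for v in silhouette(dm, part).values())


def test_silhouette_hand_computed_fixture():
    """Six samples on a line; direct (b - a)/max(a, b) per sample."""
    pts = {"a": 0.0, "b": 1.0, "c": 2.0, "d": 10.0, "e": 11.0, "f": 12.0}
    dm = dm_from_points({k: complex(v) for k, v in pts.items()})
    part = pam(dm, 2)
    sil = silhouette(dm, part)
    ids = list(pts)
    for s in ids:
        own = [t for t in ids if part.labels[t] == part.labels[s] and t != s]
        other = [t for t in ids if part.labels[t] != part.labels[s]]
        a = np.mean([abs(pts[s] - pts[t]) for t in own])
        b = np.mean([abs(pts[s] - pts[t]) for t in other])
        assert sil[s] == pytest.approx((b - a) / max(a, b), abs=1e-9)


def test_silhouette_boundary_sample_zero():
    dm = dm_from_points({"a": 0, "b": 1, "mid": 5, "c": 9, "d": 10})
    part = pam(dm, 2)
    # "mid" is equidistant from both cluster means; its score is near 0
    assert abs(silhouette(dm, part)["mid"]) < 0.15


# ------------------------------------------------------------ pooled set grid

def test_enumerate_pooled_sets_counts():
    combos = enumerate_pooled_sets(["con", "24h", "48h", "72h", "14d"])
    by_size = {}
    for c in combos:
        by_size[len(c)] = by_size.get(len(c), 0) + 1
    assert by_size == {2: 10, 3: 10, 4: 5, 5: 1}
    assert len(combos) == 26


@pytest.mark.parametrize("n,expected", [(2, 1), (4, 11)])
def test_enumerate_pooled_sets_binomial(n, expected):
    assert len(enumerate_pooled_sets([f"t{i}" for i in range(n)])) == expected


def _cohort_grid(seed, effects=None, template=None):
    from enteroshift.synthetic import build_template

    template = template or build_template(n_genera=120, seed=seed)
    design = SyntheticDesign.default(seed=seed)
    table, truth = simulate_cohort(design, template, effects or EffectModel())
    panel = select_marker_panel(table, 0.01)
    ab = percentages(table, panel, pseudocount=0)
    meta = table.metadata
    controls = meta[meta.is_control].index.tolist()
    ab_sets = {"con": ab.subset(controls)}
    for tp in ("24h", "48h", "72h", "14d"):
        ab_sets[tp] = ab.subset(meta[meta.time_point == tp].index.tolist())
    reference = {s: truth.enterotype_of_rat[s.rsplit("_", 1)[0]] for s in controls}
    grid = stability_grid(ab_sets, reference, seed=seed)
    return grid, truth, meta


def test_stability_grid_control_only_self_consistency():
    """Control samples keep their reference labels in every combination they
    enter, and cells are absent exactly for samples outside the combination."""
    grid, truth, meta = _cohort_grid(23)
    controls = meta[meta.is_control].index
    row = "con_24h"
    for s in grid.S.columns:
        in_combo = s in controls or meta.loc[s, "time_point"] == "24h"
        assert pd.isna(grid.S.loc[row, s]) == (not in_combo)
    for s in controls:
        labels = grid.cluster_of[s].dropna() if grid.cluster_of[s].notna().any() else []
        votes = call_enterotype(grid, s)
        assert votes.decision == truth.enterotype_of_rat[s.rsplit("_", 1)[0]]


def test_stability_grid_planted_shift_flips_third_dose(template):
    """An E2-ward composition planted at dose 3 flips the harmonized label of
    triple-dosed E1 samples at 72 h but not their controls."""
    effects = shift_effects(template, strength=1.0, half_life_days=1.0)
    grid, truth, meta = _cohort_grid(29, effects=effects, template=template)
    flipped = 0
    total = 0
    for rat, ent in truth.enterotype_of_rat.items():
        if ent != "E1" or meta.loc[f"{rat}_0h", "group"] != "multiple":
            continue
        total += 1
        call_ctrl = call_enterotype(grid, f"{rat}_0h")
        call_72 = call_enterotype(grid, f"{rat}_72h")
        assert call_ctrl.decision == "E1"
        if call_72.decision == "E2":
            flipped += 1
    assert total >= 10
    assert flipped / total >= 0.8


# ------------------------------------------------------------------- the vote

def _toy_grid(s_values, labels):
    rows = [f"c{i}" for i in range(len(s_values))]
    S = pd.DataFrame({"x": s_values}, index=rows)
    C = pd.DataFrame({"x": labels}, index=rows)
    return SilhouetteGrid([(r,) for r in rows], S, C)


def test_vote_unanimous():
    g = _toy_grid([0.4, 0.4, 0.4], ["E2", "E2", "E2"])
    call = call_enterotype(g, "x")
    assert call.decision == "E2"
    assert call.votes == {"E2": 3}


def test_vote_all_below_threshold_unstable():
    g = _toy_grid([0.1, 0.05, -0.2], ["E1", "E1", "E1"])
    assert call_enterotype(g, "x").decision == "unstable"


def test_vote_tie_unstable():
    g = _toy_grid([0.3] * 4, ["E1", "E1", "E2", "E2"])
    assert call_enterotype(g, "x").decision == "unstable"


def test_vote_unknown_sample():
    g = _toy_grid([0.3], ["E1"])
    with pytest.raises(KeyError):
        call_enterotype(g, "nope")


# ----------------------------------------------------------------------- PCoA

def test_pcoa_equilateral_triangle():
    d = np.ones((3, 3)) - np.eye(3)
    dm = DistanceMatrix(["a", "b", "c"], d)
    coords = pcoa_coordinates(dm, 2)
    dists = sorted(
        np.hypot(*(coords.loc[i] - coords.loc[j])) for i, j in [("a", "b"), ("a", "c"), ("b", "c")]
    )
    assert dists[0] == pytest.approx(dists[-1], rel=1e-6)


def test_pcoa_reconstructs_distances():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(6, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
    coords = pcoa_coordinates(dm, 5)
    rec = np.sqrt(((coords.values[:, None] - coords.values[None]) ** 2).sum(-1))
    assert np.allclose(rec, d, atol=1e-6)


def test_pcoa_duplicates_coincide():
    dm = dm_from_points({"a": 0, "a2": 0, "b": 4, "c": 7})
    coords = pcoa_coordinates(dm, 2)
    assert np.allclose(coords.loc["a"], coords.loc["a2"], atol=1e-8)
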