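import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enteroshift.abundance import percentages
from enteroshift.differential import (
    PairingError,
    PairSet,
    apply_inclusion_filter,
    build_pairs,
    compute_fcr,
    concordance,
    overlap_summary,
    volcano_table,
    z_statistic,
    DifferentialResult,
)

from conftest import make_table


def meta_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "rat_id", "group", "time_point", "environment", "is_control", "known_enterotype"],
    ).set_index("sample_id")
    df.index.name = None
    return df


# ---------------------------------------------------------------- build_pairs

def test_dosing_pairs_single_rat_all_timepoints():
    rows = [(f"r1_{tp}", "r1", "single", tp, "fecal", tp == "0h", "E2")
            for tp in ("0h", "24h", "48h", "72h", "14d")]
    pairs = build_pairs(meta_frame(rows), "dosing")
    flat = [p for ps in pairs for p in ps.pairs]
    assert len(flat) == 4
    assert all(c == "r1_0h" for c, _ in flat)


def test_recovery_pairs_reuse_control():
    rows = [(f"r1_{tp}", "r1", "single", tp, "fecal", tp == "0h", "E2")
            for tp in ("0h", "24h", "48h", "72h", "14d")]
    pairs = build_pairs(meta_frame(rows), "recovery")
    flat = [p for ps in pairs for p in ps.pairs]
    # 24h reflects the dose itself; 48h/72h/14d are recovery points
    assert len(flat) == 3
    assert {c for c, _ in flat} == {"r1_0h"}


def test_multiple_group_recovery_only_14d():
    rows = [(f"m1_{tp}", "m1", "multiple", tp, "fecal", tp == "0h", "E1")
            for tp in ("0h", "24h", "48h", "72h", "14d")]
    dosing = build_pairs(meta_frame(rows), "dosing")
    labels = {ps.group_label for ps in dosing}
    assert labels == {"dose-1/24h", "dose-2/48h", "dose-3/72h", "dose-3/14d"}
    recovery = build_pairs(meta_frame(rows), "recovery")
    assert [ps.group_label for ps in recovery] == ["recovery/14d"]


def test_in_vitro_pairs_and_exclusion():
    rows = [
        ("6s_GM", "6s", "single", "24h", "GMM", False, "E1"),
        ("6s_Pr", "6s", "single", "24h", "GMM_probiotic", False, "E1"),
        ("5m_GM", "5m", "single", "24h", "GMM", False, "E1"),
        ("5m_Pr", "5m", "single", "24h", "GMM_probiotic", False, "E1"),
    ]
    pairs = build_pairs(meta_frame(rows), "in_vitro")
    flat = [p for ps in pairs for p in ps.pairs]
    assert ("6s_GM", "6s_Pr") in flat and len(flat) == 2
    # the suspect culture pair is dropped when excluded
    pairs = build_pairs(meta_frame(rows), "in_vitro", exclude=[("5m_GM", "5m_Pr")])
    flat = [p for ps in pairs for p in ps.pairs]
    assert flat == [("6s_GM", "6s_Pr")]


def test_missing_control_raises():
    rows = [("r1_24h", "r1", "single", "24h", "fecal", False, "E2")]
    with pytest.raises(PairingError):
        build_pairs(meta_frame(rows), "dosing")


# ---------------------------------------------------------------------- FCR

def _toy_ab():
    # control: A 0.5%, experimental: A 2.0%
    t = make_table({
        "c": {"A": 50, "B": 9950},
        "e": {"A": 200, "B": 9800},
    })
    return percentages(t, ["A", "B"], pseudocount=1)


def test_fcr_arithmetic():
    ab = _toy_ab()
    rec = compute_fcr(ab, PairSet([("c", "e")], "toy"))
    a = rec[rec.genus == "A"].iloc[0]
    assert a.fcr == pytest.approx(4.0)
    b = rec[rec.genus == "B"].iloc[0]
    assert b.fcr == pytest.approx(9800 / 9950 * (10000 / 10000), rel=1e-6)


def test_fcr_identity_and_reciprocal():
    ab = _toy_ab()
    fwd = compute_fcr(ab, PairSet([("c", "e")], "f")).set_index("genus")["fcr"]
    rev = compute_fcr(ab, PairSet([("e", "c")], "r")).set_index("genus")["fcr"]
    for g in ("A", "B"):
        assert fwd[g] == pytest.approx(1.0 / rev[g])


def test_fcr_pseudocount_keeps_finite():
    t = make_table({"c": {"A": 0, "B": 10000}, "e": {"A": 500, "B": 9500}})
    ab = percentages(t, ["A", "B"], pseudocount=1)
    rec = compute_fcr(ab, PairSet([("c", "e")], "x"))
    fcr = rec[rec.genus == "A"].iloc[0].fcr
    assert np.isfinite(fcr) and fcr > 100


def test_fcr_requires_pseudocount():
    t = make_table({"c": {"A": 1, "B": 9}})
    ab = percentages(t, ["A", "B"], pseudocount=0)
    with pytest.raises(ValueError):
        compute_fcr(ab, PairSet([("c", "c")], "x"))


# ----------------------------------------------------------- inclusion filter

def _records(rows):
    return pd.DataFrame(
        rows, columns=["genus", "control", "experimental", "control_pct", "experimental_pct", "fcr"]
    )


def test_filter_below_floor_excluded():
    rows = [("g", f"c{i}", f"e{i}", 0.005, 0.005, 1.0) for i in range(5)]
    assert apply_inclusion_filter(_records(rows)) == {}


def test_filter_exactly_three_qualifying_included():
    rows = [("g", f"c{i}", f"e{i}", 0.5, 1.0, 2.0) for i in range(3)]
    kept = apply_inclusion_filter(_records(rows))
    assert set(kept) == {"g"} and len(kept["g"]) == 3


def test_filter_direction_dependent_side():
    # increased pairs qualify on the experimental side, suppressed on control
    rows = [
        ("g", "c1", "e1", 0.005, 0.02, 4.0),   # qualifies (exp >= 0.01)
        ("g", "c2", "e2", 0.02, 0.005, 0.25),  # qualifies (ctrl >= 0.01)
        ("g", "c3", "e3", 0.005, 0.008, 1.6),  # fails: exp < 0.01
    ]
    kept = apply_inclusion_filter(_records(rows), min_pairs=2)
    assert len(kept["g"]) == 2
    rows[1] = ("g", "c2", "e2", 0.005, 0.001, 0.2)  # now fails too
    assert apply_inclusion_filter(_records(rows), min_pairs=2) == {}


# ---------------------------------------------------------------- z statistic

def test_z_null_gives_half():
    r = z_statistic([1.0, 1.0, 1.0, 1.0])
    assert r.z == 0.0 and r.p == 0.5
    r = z_statistic([1.2, 0.8, 1.1, 0.9])
    assert r.p == pytest.approx(0.5, abs=0.4)


def test_z_constant_nonnull_fcr_degenerate():
    r = z_statistic([2.0, 2.0, 2.0])
    assert r.degenerate and r.p is None  # sd = 0 off the null: flagged, p omitted


def test_z_strong_effect_closed_form():
    fcrs = [2.001, 1.999, 2.002, 1.998]
    x = np.array(fcrs)
    z_expected = (x.mean() - 1) / (x.std(ddof=1) / 2)
    r = z_statistic(fcrs)
    assert r.z == pytest.approx(z_expected)
    assert r.p < 0.001 and r.direction == "stimulated"


def test_z_large_no_underflow():
    r = z_statistic([2.0, 2.0000001, 1.9999999, 2.0])
    assert r.z is not None and abs(r.z) > 10
    assert r.p is not None and 0 < r.p < 1e-20


def test_z_sd_denominator_option():
    fcrs = [1.5, 1.4, 1.6, 1.5]
    sem = z_statistic(fcrs, use_sem=True)
    sd = z_statistic(fcrs, use_sem=False)
    assert sem.z == pytest.approx(sd.z * 2)  # sqrt(n) = 2


@given(st.permutations(range(6)))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_z_invariant_under_pair_permutation(perm):
    base = [1.3, 0.7, 1.8, 0.9, 1.1, 2.2]
    r0 = z_statistic(base)
    r1 = z_statistic([base[i] for i in perm])
    assert r1.z == pytest.approx(r0.z)


def test_z_needs_three_pairs():
    with pytest.raises(ValueError):
        z_statistic([1.0, 2.0])


# -------------------------------------------------------------------- volcano

def test_volcano_tiers_and_axes():
    rs = [
        z_statistic([2.0, 2.1, 1.9, 2.05], genus="up"),
        z_statistic([1.05, 0.95, 1.02, 0.99], genus="flat"),
    ]
    v = volcano_table(rs).set_index("genus")
    assert v.loc["up", "tier"] == "strong"
    assert v.loc["flat", "log2_mean_fcr"] == pytest.approx(math.log2(np.mean([1.05, 0.95, 1.02, 0.99])))
    # p ordering mirrors |z| ordering
    assert (v.sort_values("p").index == v.sort_values("z", key=abs, ascending=False).index).all()


def test_volcano_mean_one_at_origin():
    r = DifferentialResult("g", "grp", 3, 1.0, 0.2, 0.0, 0.5, "stimulated")
    v = volcano_table([r])
    assert v.iloc[0].log2_mean_fcr == pytest.approx(0.0)
    assert v.iloc[0].tier == "ns"


# ---------------------------------------------------------------- concordance

def _res(genus, direction, p):
    return DifferentialResult(genus, "x", 5, 2.0 if direction == "stimulated" else 0.5, 0.1, 3.0, p, direction)


def test_concordance_labels():
    a = [_res("g1", "stimulated", 0.01), _res("g2", "stimulated", 0.01), _res("g3", "stimulated", 0.01)]
    b = [_res("g1", "stimulated", 0.02), _res("g2", "suppressed", 0.02), _res("g3", "stimulated", 0.5)]
    lab = concordance(a, b).set_index("genus")["label"]
    assert lab["g1"] == "similar"
    assert lab["g2"] == "opposite"
    assert lab["g3"] == "none"


# -------------------------------------------------------------------- overlap

def test_overlap_disjoint_and_full():
    u = [f"g{i}" for i in range(10)]
    assert overlap_summary(u[:5], u[5:], u).observed == 0
    full = overlap_summary(u, u, u)
    assert full.observed == full.expected == 10


def test_overlap_expected_by_chance():
    # 13 responders against a 46.2% inhibited background: expect ~6 shared
    u = [f"g{i}" for i in range(1000)]
    b = u[: int(0.462 * 1000)]
    a = u[500:513]
    s = overlap_summary(a, b, u)
    assert s.expected == pytest.approx(13 * 462 / 1000)
    assert round(s.expected) == 6


def test_overlap_empty_universe():
    with pytest.raises(ValueError):
        overlap_summary([], [], [])
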