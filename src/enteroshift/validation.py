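"""Replicate recovery studies on synthetic cohorts.

These are the calibration experiments the package runs on itself: can the
clustering stack recover planted enterotypes from sequencing noise alone,
can the paired fold-change statistic find planted effects with the right
sign, and how often does it fire under the null.  Both the test suite and
the reproduction script drive these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import differential as da
from . import enterotypes as et
from .abundance import percentages, select_marker_panel
from .synthetic import (
    EffectModel,
    SyntheticDesign,
    build_template,
    simulate_cohort,
)

__all__ = [
    "RecoveryStudy",
    "enterotype_recovery",
    "effect_detection",
    "null_false_positive_rate",
]


@dataclass
class RecoveryStudy:
    rate: float  # fraction in [0, 1]
    n: int  # units scored (rats, replicates, or genus-groups)


def _cluster_accuracy(labels: dict[str, int], truth: dict[str, str]) -> float:
    """Best-of-two-mappings agreement between cluster ids and enterotypes."""
    samples = list(labels)
    hits = {m: 0 for m in (0, 1)}
    for s in samples:
        want_e1 = truth[s] == "E1"
        is_zero = labels[s] == 0
        hits[0] += int(want_e1 == is_zero)
        hits[1] += int(want_e1 != is_zero)
    return max(hits.values()) / len(samples)


def enterotype_recovery(
    n_replicates: int = 200,
    seed: int = 0,
    depth: int = 30000,
    n_genera: int = 220,
    threshold_percent: float = 0.01,
) -> RecoveryStudy:
    """Zero-effect cohorts: PAM(k=2) on JSD of control samples vs truth.

    Each replicate draws a fresh template and a fresh 21-rat cohort (control
    samples only), builds the marker panel, clusters, and scores the
    fraction of rats assigned to their planted enterotype under the better
    of the two cluster-to-enterotype mappings.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(2 * n_replicates).astype(np.int64) % (2**31)
    correct = 0
    total = 0
    for r in range(n_replicates):
        template = build_template(n_genera=n_genera, seed=int(rep_seeds[2 * r]))
        design = SyntheticDesign.default(seed=int(rep_seeds[2 * r + 1]), depth=depth)
        design.time_points = ("0h",)
        table, truth = simulate_cohort(design, template, EffectModel())
        panel = select_marker_panel(table, threshold_percent)
        ab = percentages(table, panel, pseudocount=0)
        dm = et.jsd_distance(ab)
        part = et.pam(dm, 2, seed=int(rep_seeds[2 * r]))
        sample_truth = {s: truth.enterotype_of_rat[s.rsplit("_", 1)[0]] for s in part.labels}
        acc = _cluster_accuracy(part.labels, sample_truth)
        correct += round(acc * len(part.labels))
        total += len(part.labels)
    return RecoveryStudy(correct / total, total)


def effect_detection(
    n_replicates: int = 200,
    seed: int = 0,
    depth: int = 30000,
    n_pairs: int = 6,
    log2_effect: float = 2.0,
    n_genera: int = 220,
) -> RecoveryStudy:
    """Planted symmetric 4-fold effects vs the paired FCR Z-test.

    Each replicate simulates ``n_pairs`` single-dose E1 rats sampled at 0 h
    and 24 h, plants a +log2_effect on one mid-abundance genus and
    -log2_effect on another, runs the differential pipeline, and scores the
    replicate as a success when both planted genera come out at p <= 0.001
    with the correct direction.
    """
    ss = np.random.SeedSequence(seed + 1)
    rep_seeds = ss.generate_state(2 * n_replicates).astype(np.int64) % (2**31)
    hits = 0
    for r in range(n_replicates):
        template = build_template(n_genera=n_genera, seed=int(rep_seeds[2 * r]))
        conc = template.base_concentration["E1"]
        # carriers near 0.5% expected abundance: detectable but not dominant
        order = np.argsort(np.abs(conc - 0.005))
        up, down = template.genus_names[order[0]], template.genus_names[order[1]]
        effects = EffectModel(
            {(up, "E1", 1): log2_effect, (down, "E1", 1): -log2_effect},
            {up: 50.0, down: 50.0},
        )
        design = SyntheticDesign(
            {"E1": n_pairs},
            {f"E1_r{i + 1:02d}": "single" for i in range(n_pairs)},
            time_points=("0h", "24h"),
            depth=depth,
            seed=int(rep_seeds[2 * r + 1]),
        )
        table, _ = simulate_cohort(design, template, effects)
        panel = select_marker_panel(table, 0.01)
        ab = percentages(table, panel, pseudocount=1)
        pairsets = da.build_pairs(table.metadata, "dosing")
        results = {
            res.genus: res
            for ps in pairsets
            for res in da.differential_table(ab, ps, panel)
        }
        ok = True
        for genus, want in ((up, "stimulated"), (down, "suppressed")):
            res = results.get(genus)
            if res is None or res.degenerate or res.p is None:
                ok = False
            elif res.p > 0.001 or res.direction != want:
                ok = False
        hits += int(ok)
    return RecoveryStudy(hits / n_replicates, n_replicates)


def null_false_positive_rate(
    n_groups: int = 2000,
    seed: int = 0,
    depth: int = 30000,
    n_genera: int = 220,
) -> RecoveryStudy:
    """Fraction of genus-groups reaching p < 0.05 with no planted effects.

    Full default cohorts (21 rats, five time points) are simulated with a
    null effect model and pushed through the dosing-scheme differential
    pipeline; every (genus, pair group) Z-test is one unit.  Cohorts are
    accumulated until at least ``n_groups`` tests are available.
    """
    ss = np.random.SeedSequence(seed + 2)
    pvals: list[float] = []
    batch = 0
    while len(pvals) < n_groups:
        seeds = ss.generate_state(2).astype(np.int64) % (2**31)
        template = build_template(n_genera=n_genera, seed=int(seeds[0]))
        design = SyntheticDesign.default(seed=int(seeds[1]), depth=depth)
        table, _ = simulate_cohort(design, template, EffectModel())
        panel = select_marker_panel(table, 0.01)
        ab = percentages(table, panel, pseudocount=1)
        for ps in da.build_pairs(table.metadata, "dosing"):
            # restrict each group to its own enterotype's samples
            for res in da.differential_table(ab, ps, panel):
                if not res.degenerate and res.p is not None:
                    pvals.append(res.p)
        batch += 1
        if batch > 20:  # pragma: no cover - safety valve
            break
    pvals = pvals[:n_groups] if len(pvals) >= n_groups else pvals
    arr = np.asarray(pvals)
    return RecoveryStudy(float((arr < 0.05).mean()), len(arr))
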