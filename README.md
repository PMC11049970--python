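# enteroshift

Enterotype clustering and probiotic-response analysis for genus-level 16S
read-count tables, with a synthetic two-enterotype cohort generator.

`enteroshift` is aimed at microbiome researchers who profile gut communities
(rat or otherwise) at the genus level with amplicon sequencing and want to
(1) call discrete community types — *enterotypes* — and judge how robust
each sample's call is, and (2) quantify how a paired intervention (e.g. a
probiotic given to the same animals whose baseline was sampled) shifts
individual genera.

## The methods at its core

**Enterotyping.** Samples are compared by the root Jensen–Shannon divergence
of their renormalized genus profiles,

&nbsp;&nbsp;&nbsp;&nbsp;d(i, j) = √( ½·KL(pᵢ‖m) + ½·KL(pⱼ‖m) ),&nbsp; m = ½(pᵢ + pⱼ),

restricted to a *marker panel*: the union of genera reaching a relative
abundance threshold (default 0.01 %) in at least one sample. Clusters come
from partition-around-medoids (PAM, BUILD + SWAP); the number of clusters is
scanned with a medoid-based Calinski–Harabasz index CH(k) = (B/(k−1)) /
(W/(n−k)). Stability of the two-cluster call is probed by re-clustering
every pooled combination of the time-point sample sets (5 sets → 10 pairs,
10 triplets, 5 quartets, 1 quintet) and counting, per sample, in how many
combinations it lands in each harmonized enterotype with silhouette
S > 0.1; the majority of those "true" assignments is the final call, with
ties reported as *unstable*.

**Paired differential response.** For each genus g and control/treated pair,
the fold-change ratio FCR = treated % / control % is computed after adding a
single pseudocount read to zero cells. Pairs qualify when the relevant side
(treated for increases, control for decreases) is ≥ 0.01 %; genera with ≥ 3
qualifying pairs are tested with a one-sample Z statistic against FCR = 1,

&nbsp;&nbsp;&nbsp;&nbsp;z = (mean(FCR) − 1) / (sd(FCR)/√n),&nbsp;&nbsp; p = 1 − Φ(|z|),

evaluated with the complementary error function so extreme z never
underflows. Shannon diversity, representative-taxon selection for
composition profiles (greedy, five rounds over a ten-profile order, with a
normalizing sector N equalizing profile totals) and chance-expected Venn
overlaps round out the toolkit.

**Synthetic cohorts.** The generator emulates the study design the analysis
assumes: 21 rats split 14/7 into two enterotypes that differ in
Bacteroidota/Bacillota balance and Verrucomicrobiota content, single- vs
triple-dose probiotic schedules sampled at 0/24/48/72 h and 14 d,
rat-level individuality (Dirichlet), multinomial sequencing noise at 30,000
reads/sample, and planted, dose-dependent, enterotype-specific effects —
including lactobacilli expansion and bifidobacteria suppression in the E2
biota — with exponential post-treatment decay. Ground truth is exported so
recovery can be scored.

## Worked example

```python
from enteroshift import (
    build_pairs, build_template, ch_scan, differential_table, jsd_distance,
    pam, percentages, select_marker_panel, simulate_cohort,
)
from enteroshift.synthetic import SyntheticDesign, default_effects

template = build_template(seed=1)
design = SyntheticDesign.default(seed=1)
table, truth = simulate_cohort(design, template, default_effects(template, seed=1))

panel = select_marker_panel(table, threshold_percent=0.01)
controls = table.metadata[table.metadata.is_control].index.tolist()
dm = jsd_distance(percentages(table, panel).subset(controls))
scan = ch_scan(dm, range(2, 6))
part = pam(dm, k=2, seed=1)
print("CH:", {k: round(v, 1) for k, v in scan.ch_index.items()},
      "-> optimal k =", scan.optimal_k)
print("cluster sizes:", {c: len(part.members(c)) for c in part.medoids})

ab1 = percentages(table, panel, pseudocount=1)
ps = [p for p in build_pairs(table.metadata, "dosing")
      if p.enterotype == "E2" and p.group_label == "dose-1/24h"][0]
res = {r.genus: r for r in differential_table(ab1, ps, panel)}
for g in ("Lacticaseibacillus", "Bifidobacterium"):
    r = res[g]
    print(g, r.n, round(r.mean_fcr, 2), round(r.z, 2), f"{r.p:.2e}", r.direction)
```

prints

```
CH: {2: 37.5, 3: 18.8, 4: 11.0, 5: 8.4} -> optimal k = 2
cluster sizes: {0: 14, 1: 7}
Lacticaseibacillus 6 2.88 8.73 1.28e-18 stimulated
Bifidobacterium 6 0.39 -9.14 3.13e-20 suppressed
```

The Calinski–Harabasz scan selects two enterotypes, the PAM partition
recovers the planted 14/7 split, and one probiotic dose in the E2 cohort
expands lactobacilli ~2.9-fold while suppressing bifidobacteria to ~0.4 of
control — the planted response structure, with one of the seven pairs
dropped by the inclusion filter.

A full run (simulate → panel → enterotype → stability grid → calls →
differential → diversity → selection → report) is one command:

```sh
enteroshift run --seed 1 --out my_run/
```

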