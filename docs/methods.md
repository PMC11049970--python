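# Methods

This note documents the models and procedures implemented in `enteroshift`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Enterotyping stack

**Distance.** Root Jensen–Shannon divergence between per-sample genus
proportions over the marker panel. Zeros are replaced by a pseudo value
(default 1e-10 on proportions, the convention of the classical enterotyping
scripts) and rows renormalized before taking logs; natural log is the
default base (bounded by √ln 2 ≈ 0.8326), base 2 available. The pseudo
value only matters for genera absent from one sample of a pair; at 1e-10 it
contributes negligibly to the divergence while keeping it finite.

**Marker panel.** Union of genera at ≥ 0.01 % relative abundance in at
least one sample, ordered by descending maximal abundance with lexicographic
tie-break. The threshold is configurable: 0.01 % is the permissive default,
and 0.1 % is a supported stricter alternative — both thresholds are in
circulation for this kind of panel and the choice is a screening decision,
not a statistical one. "In at least one dataset" is interpreted per sample
(each sequencing library is one dataset).

**Clustering.** PAM with deterministic greedy BUILD initialization and
steepest-descent SWAP; the seed only permutes tie-breaking among equal-cost
swaps, so results are reproducible. The final total distance to medoids is a
local optimum under single-medoid swaps and, on every test fixture with
n ≤ 8, equals the exhaustive optimum over all medoid sets.

**Cluster number.** A Calinski–Harabasz scan adapted to distance matrices:
between-cluster dispersion B = Σ n_c·d(m_c, m\*)² over cluster medoids m_c
and the global medoid m\*, within-cluster W = Σ d(i, m_c(i))², CH(k) =
(B/(k−1))/(W/(n−k)), k from 2 to 5. The scan is exploratory; the stability
machinery fixes k = 2, the regime the two-enterotype analysis targets.

**Silhouette and the vote.** Per-sample silhouette S = (b−a)/max(a,b) on
the precomputed distances (singletons score 0). Every pooled combination of
the time-point sample sets (all subsets of size ≥ 2; five sets give 26
combinations) is re-clustered from scratch, its two clusters are renamed
E1/E2 by majority overlap of member control samples with the control-only
reference partition, and a sample votes for its harmonized label in each
combination where S > 0.1. The decision is the majority label; ties and
zero votes yield *unstable* — the conservative reading of a vote rule that
defines "true assignments" without a tie rule. How to harmonize cluster
identity across combinations is genuinely open; majority overlap with the
control reference was chosen because it is label-invariant and reduces to
identity on the control-only combination. Heatmap exports encode S × 100
rounded to integers.

**Ordination.** Classical PCoA (via scikit-bio) of the JSD matrix; negative
eigenvalues are truncated with a logged note.

## Paired fold-change statistics

FCRs are computed on percentages built with a single pseudocount read added
to zero-count panel cells, so every ratio is finite and reversal of a pair
inverts the ratio exactly. Inclusion filtering is direction-aware: a pair
counts for an increased genus only if the treated percentage is ≥ 0.01 %
and for a suppressed genus only if the control percentage is ≥ 0.01 %;
genera need ≥ 3 qualifying pairs. The test statistic is a one-sample Z
against FCR = 1 with the standard-error denominator sd/√n; the description
"Z-score with FCR = 1 as the null hypothesis parameter" is ambiguous
between sd and sd/√n, and the test-like reading (sd/√n) is the default with
`use_sem=False` switching to sd. The p-value is one-sided in the observed
direction, p = 1 − Φ(|z|), computed via the complementary error function so
that z = 10 or larger yields a finite positive p. FCRs are tested on the
raw ratio scale; no multiple-testing correction is applied to the headline
tiers (p ≤ 0.001 "strong", p < 0.05 "significant") — a Benjamini–Hochberg
column can be derived by the user but is not part of the decision rule.
sd = 0 with mean ≠ 1 is flagged degenerate (p omitted); all-FCR-exactly-1
returns z = 0, p = 0.5.

**Calibration at small n (known limitation).** The rejection rule
|z| > Φ⁻¹(0.95) has *nominal* two-direction level 0.10, and because sd is
estimated from n = 3–14 pairs, the actual null rate follows t-distribution
tails: P(|t₆| > 1.645) ≈ 0.15, P(|t₁₃| > 1.645) ≈ 0.12. Measured on
simulated null cohorts the fraction of genus-groups at p < 0.05 is
0.12–0.15, consistent with that arithmetic. The p ≤ 0.001 tier used for
headline calls is far less affected, which is why the planted-effect
detection study passes cleanly at that tier. Users who need calibrated
p < 0.05 decisions at small n should treat the 0.05 tier as a screening
threshold or use the sd/√n statistic with a t reference themselves.

**Concordance and overlaps.** Two result sets are compared genus-wise:
*similar* means significant (p < 0.05) in both with the same direction,
*opposite* significant in both with discordant directions. Venn overlaps
are compared to the chance expectation |A|·|B|/|U| with a hypergeometric
upper-tail p attached as advisory only.

## Diversity and representative selection

Shannon H′ = −Σ p·log p over detected genera, base 2 by default (scikit-bio
implementation). The identified-taxon count uses a ≥ 1 read detection
floor. Group comparisons gate on Shapiro–Wilk normality at 0.05 in both
groups: Student's t if both pass, Wilcoxon rank-sum otherwise; constant
groups are flagged degenerate.

The candidate pool for composition profiles contains genera with a
statistically significant (p < 0.05) ≥ 2-fold response (in either
direction) at ≥ 1 time point that pass the inclusion filters in every
compared set. Selection is stepwise-greedy: cycling a fixed profile order
(interleaved E1/E2 trajectories across time points), each step takes the
not-yet-selected pool genus with maximal percentage in the current profile;
ties break lexicographically, making the output deterministic. Five rounds
over ten profiles yield 50 taxa; the dominant selected genus of each
control profile is then removed post hoc (a shared dominant is removed
once) and the normalizing sector N(profile) = max total − total pads every
profile to a common total.

## Synthetic cohort generator

The generator defines the study conditions for all recovery tests.

* **Community templates.** Two enterotype composition vectors over ~220
  genera in five phyla. Default phylum targets: E1 = 57 % Bacteroidota,
  27.7 % Bacillota (B/F 2.06), 10 % Pseudomonadota, 0.3 % Verrucomicrobiota,
  5 % Actinomycetota; E2 = 55/26.2 (B/F 2.1)/8/6.8/4. Both enterotypes are
  Bacteroidota/Bacillota dominated; the Verrucomicrobiota fraction and
  independent within-phylum lognormal (σ = 1.5) rank-abundance profiles are
  what separate them at the genus level. The probiotic genera
  (*Lacticaseibacillus*, *Bifidobacterium*) are placed deterministically at
  their phylum's mean weight so planted probiotic effects always have a
  detectable carrier. Phylum mass fractions match targets exactly by
  construction.
* **Design.** 21 rats (14 E1, 7 E2); all E2 rats and two E1 rats single
  dose, twelve E1 rats three doses at 24 h intervals; sampling at 0 (control),
  24, 48, 72 h and 14 d; 30,000 reads/sample — desk-scale, yet small enough
  sampling noise that 0.01 % thresholds are genuinely exercised.
* **Rat individuality.** Baseline = Dirichlet(overdispersion × template),
  overdispersion 200 by default. No quantitative within-enterotype
  dispersion is available to fit, so this is a free parameter exposed in the
  config; 200 gives clearly individual yet cleanly clusterable controls.
* **Effects.** Planted log2 effects indexed by (genus, enterotype, dose).
  Each dose contributes its full effect for 24 h and then decays
  exponentially with a genus-specific half-life (default 3 d; transient
  responders 1.5–4 d, a persistent minority 50 d, probiotic genera 20–30 d).
  Composition at time t multiplies the baseline by 2^(Σ decayed effects)
  and is renormalized; reads are multinomial. Sign-flipped responders
  (default 25 %) carry opposite signs in the two enterotypes. A helper
  plants a wholesale E1→E2 composition shift at dose 3 with a short
  half-life, the analogue of the transient collective enterotype shift at
  72 h.
* **What is not emulated.** Read-level errors, chimeras, taxonomic
  misclassification, compositional correlations between genera beyond the
  Dirichlet draw, library-size variation, and the ex-vivo (GMM) culturing
  arm — in-vitro pairing logic is exercised on hand-built metadata instead.
  Passing recovery tests therefore demonstrates correctness of the analysis
  machinery under multinomial noise and planted structure, not robustness
  to classifier artifacts or real biological covariance.

## Recovery studies (problem sizes)

* Enterotype recovery: 200 replicate control-only cohorts (21 rats each),
  fresh template and cohort per replicate; scored as the fraction of rats
  matching the planted label under the better cluster-to-label mapping.
* Effect detection: 200 replicates of 6 single-dose rats at 0/24 h; one
  genus planted at +2 log2, one at −2, carriers chosen nearest 0.5 %
  abundance; success requires both at p ≤ 0.001 with the correct sign.
* Null calibration: full null cohorts accumulated to 2000 genus-group
  Z-tests.

These sizes keep the full suite and the reproduction script fast while the
replicate counts match the study sizes stated above.

## Numerical conventions and degenerate inputs

Percentages are carried at full float precision (display rounding only at
export). Masked outlier cells are NaN and drop out of numerator and
denominator, preserving ratios among the unmasked genera exactly; masking
every genus of a sample is an error, as is a zero-read sample. B/F with
zero Bacillota reports +inf. Genus names are matched after whitespace
trimming only — no taxonomy-aware synonym resolution, since input tables
come from a single classifier's vocabulary. All tabular pipeline outputs
carry a header comment with version, config hash and seed, and every source
of randomness (simulation, PAM tie-breaks) flows from the single config
seed, so identical configs reproduce byte-identical tables.
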