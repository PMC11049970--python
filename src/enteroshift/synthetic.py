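"""Synthetic two-enterotype rat cohorts with planted probiotic effects.

The generator emulates the statistical structure the analysis assumes: a
cohort of rats whose gut communities fall into two enterotypes (E1/E2)
distinguished by phylum composition (Bacteroidota/Bacillota balance,
Verrucomicrobiota presence), a single- vs triple-dose feeding design with
fecal sampling at 0/24/48/72 h and 14 d, and dose-dependent,
enterotype-specific probiotic responses — including lactobacilli expansion
and bifidobacteria suppression in the E2 biota — that decay exponentially
after the last dose.  Sequencing is modeled as a multinomial draw of fixed
depth from each rat's perturbed composition; rat-level individuality is a
Dirichlet draw around the enterotype's template composition.

Ground truth (enterotype per rat, planted per-genus effects) is returned
alongside the count table so recovery tests can score the analysis modules.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .abundance import ReadCountTable

__all__ = [
    "CommunityTemplate",
    "EffectModel",
    "SyntheticDesign",
    "GroundTruth",
    "build_template",
    "default_phylum_targets",
    "default_effects",
    "shift_effects",
    "simulate_cohort",
    "export_ground_truth",
    "read_ground_truth",
    "load_config",
    "write_cohort",
]

ENTEROTYPES = ("E1", "E2")
TIME_HOURS = {"0h": 0.0, "24h": 24.0, "48h": 48.0, "72h": 72.0, "14d": 336.0}
#: hours between successive doses in the triple-dose group
DOSE_INTERVAL_H = 24.0
PROBIOTIC_LACTO = "Lacticaseibacillus"
PROBIOTIC_BIFIDO = "Bifidobacterium"


class InvalidTemplateError(ValueError):
    pass


@dataclass
class CommunityTemplate:
    """Per-enterotype expected community composition.

    ``base_concentration`` maps each enterotype to a strictly positive
    vector over ``genus_names``; entries are mass fractions (sum 1), scaled
    by the design's overdispersion when drawing rat baselines.
    """

    genus_names: list[str]
    phylum_of: dict[str, str]
    base_concentration: dict[str, np.ndarray]
    enterotype_labels: tuple[str, str] = ENTEROTYPES

    def __post_init__(self) -> None:
        for ent, conc in self.base_concentration.items():
            conc = np.asarray(conc, dtype=float)
            if len(conc) != len(self.genus_names):
                raise InvalidTemplateError(f"{ent}: concentration length mismatch")
            if (conc <= 0).any():
                raise InvalidTemplateError(f"{ent}: concentrations must be strictly positive")
            self.base_concentration[ent] = conc / conc.sum()
        bf = self.phylum_mass(self.enterotype_labels[0])
        dom = bf.get("Bacteroidota", 0.0) + bf.get("Bacillota", 0.0)
        if dom < 0.5:
            raise InvalidTemplateError(
                "Bacteroidota + Bacillota must dominate (>= 50% of expected mass)"
            )

    def phylum_mass(self, enterotype: str) -> dict[str, float]:
        conc = self.base_concentration[enterotype]
        out: dict[str, float] = {}
        for g, c in zip(self.genus_names, conc):
            out[self.phylum_of[g]] = out.get(self.phylum_of[g], 0.0) + float(c)
        return out


@dataclass
class EffectModel:
    """Planted per-genus, per-enterotype, per-dose log2 fold effects.

    ``half_life_days`` gives the post-treatment exponential decay half-life
    of each affected genus's response; genera absent from the map use
    ``default_half_life_days``.  A genus may carry opposite signs in the two
    enterotypes (the sign-flipped responders seen between the two biotas).
    """

    log2_effect: dict[tuple[str, str, int], float] = field(default_factory=dict)
    half_life_days: dict[str, float] = field(default_factory=dict)
    probiotic_genera: tuple[str, ...] = (PROBIOTIC_LACTO, PROBIOTIC_BIFIDO)
    default_half_life_days: float = 3.0

    def __post_init__(self) -> None:
        for (g, ent, dose), _ in self.log2_effect.items():
            if dose not in (1, 2, 3):
                raise ValueError(f"dose_index must be 1, 2 or 3 (got {dose} for {g})")
        for g, hl in self.half_life_days.items():
            if hl <= 0:
                raise ValueError(f"persistence half-life must be positive ({g})")
        if self.default_half_life_days <= 0:
            raise ValueError("default half-life must be positive")

    def genera(self) -> set[str]:
        return {g for g, _, _ in self.log2_effect}

    def half_life(self, genus: str) -> float:
        return self.half_life_days.get(genus, self.default_half_life_days)

    def true_sign(self, genus: str, enterotype: str) -> int:
        """Sign of the planted first-response effect (0 if none)."""
        for dose in (1, 2, 3):
            v = self.log2_effect.get((genus, enterotype, dose), 0.0)
            if v != 0.0:
                return 1 if v > 0 else -1
        return 0


@dataclass
class SyntheticDesign:
    """Cohort layout: rats, dosing groups, time points, sequencing depth."""

    n_rats_per_enterotype: dict[str, int]
    group_of_rat: dict[str, str] = field(default_factory=dict)
    time_points: tuple[str, ...] = ("0h", "24h", "48h", "72h", "14d")
    depth: int = 30000
    rat_overdispersion: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1000:
            raise ValueError("depth must be >= 1000 reads per sample")
        if not self.time_points or self.time_points[0] != "0h":
            raise ValueError("time points must start at 0h (the control sample)")
        for tp in self.time_points:
            if tp not in TIME_HOURS:
                raise ValueError(f"unknown time point {tp!r}")
        if not self.group_of_rat:
            self.group_of_rat = {r: "single" for r in self.rat_ids()}
        for rat, grp in self.group_of_rat.items():
            if grp not in ("single", "multiple"):
                raise ValueError(f"group of {rat} must be single or multiple")

    def rat_ids(self) -> list[str]:
        out = []
        for ent in sorted(self.n_rats_per_enterotype):
            for i in range(self.n_rats_per_enterotype[ent]):
                out.append(f"{ent}_r{i + 1:02d}")
        return out

    def enterotype_of(self, rat_id: str) -> str:
        return rat_id.split("_r")[0]

    @classmethod
    def default(cls, seed: int = 0, depth: int = 30000, rat_overdispersion: float = 200.0) -> "SyntheticDesign":
        """The study layout: 21 rats, 14 E1 / 7 E2; all E2 rats and two E1
        rats received a single dose, the other twelve E1 rats three doses."""
        groups = {}
        for i in range(14):
            groups[f"E1_r{i + 1:02d}"] = "single" if i < 2 else "multiple"
        for i in range(7):
            groups[f"E2_r{i + 1:02d}"] = "single"
        return cls({"E1": 14, "E2": 7}, groups, depth=depth,
                   rat_overdispersion=rat_overdispersion, seed=seed)


@dataclass
class GroundTruth:
    enterotype_of_rat: dict[str, str]
    effects: EffectModel

    def effect_rows(self) -> pd.DataFrame:
        rows = [
            (g, ent, dose, val, self.effects.half_life(g))
            for (g, ent, dose), val in sorted(self.effects.log2_effect.items())
        ]
        return pd.DataFrame(
            rows, columns=["genus", "enterotype", "dose_index", "log2_effect", "half_life_days"]
        )


def default_phylum_targets() -> dict[str, dict[str, float]]:
    """Expected phylum percentages per enterotype.

    Both enterotypes are Bacteroidota/Bacillota dominated with control B/F
    near 2 (2.06 in E1, 2.1 in E2); the E2 biota carries a visible
    Verrucomicrobiota fraction, the main phylum-level discriminator.
    """
    return {
        "E1": {
            "Bacteroidota": 57.0,
            "Bacillota": 27.7,
            "Pseudomonadota": 10.0,
            "Verrucomicrobiota": 0.3,
            "Actinomycetota": 5.0,
        },
        "E2": {
            "Bacteroidota": 55.0,
            "Bacillota": 26.2,
            "Pseudomonadota": 8.0,
            "Verrucomicrobiota": 6.8,
            "Actinomycetota": 4.0,
        },
    }


def build_template(
    n_genera: int = 220,
    phylum_targets: Mapping[str, Mapping[str, float]] | Mapping[str, float] | None = None,
    seed: int = 0,
) -> CommunityTemplate:
    """Random community template honoring per-enterotype phylum targets.

    Genera are apportioned to phyla proportionally to their expected mass;
    within a phylum, rank-abundance heterogeneity comes from lognormal
    weights drawn independently for the two enterotypes (so the enterotypes
    differ at the genus level, not only in phylum balance).  The probiotic
    genera are placed deterministically so planted probiotic effects always
    have a carrier.  Phylum mass fractions match the targets exactly.
    """
    if phylum_targets is None:
        phylum_targets = default_phylum_targets()
    first = next(iter(phylum_targets.values()))
    if not isinstance(first, Mapping):  # one shared map for both enterotypes
        phylum_targets = {ent: dict(phylum_targets) for ent in ENTEROTYPES}
    targets = {ent: dict(m) for ent, m in phylum_targets.items()}
    for ent, m in targets.items():
        total = sum(m.values())
        if abs(total - 100.0) > 0.1:
            raise InvalidTemplateError(f"{ent} phylum targets sum to {total}, not 100")
    phyla = sorted({p for m in targets.values() for p in m})
    if n_genera < len(phyla):
        raise InvalidTemplateError("need at least one genus per phylum")

    rng = np.random.default_rng(seed)
    # apportion genera to phyla by average target mass (>= 1 each)
    avg_mass = np.array([
        np.mean([targets[ent].get(p, 0.0) for ent in targets]) for p in phyla
    ])
    ideal = avg_mass / avg_mass.sum() * n_genera
    counts = np.maximum(1, np.floor(ideal).astype(int))
    remainder_order = np.argsort(-(ideal - np.floor(ideal)))
    j = 0
    while counts.sum() < n_genera:
        counts[remainder_order[j % len(phyla)]] += 1
        j += 1
    while counts.sum() > n_genera:
        i = int(np.argmax(counts))
        counts[i] -= 1

    genus_names: list[str] = []
    phylum_of: dict[str, str] = {}
    for p, c in zip(phyla, counts):
        for i in range(c):
            name = f"{p}_g{i + 1:03d}"
            genus_names.append(name)
            phylum_of[name] = p
    # deterministic carriers for the two probiotic genera
    renames = {}
    if "Bacillota" in phyla:
        renames[f"Bacillota_g001"] = PROBIOTIC_LACTO
    if "Actinomycetota" in phyla:
        renames[f"Actinomycetota_g001"] = PROBIOTIC_BIFIDO
    genus_names = [renames.get(g, g) for g in genus_names]
    phylum_of = {renames.get(g, g): p for g, p in phylum_of.items()}

    conc: dict[str, np.ndarray] = {}
    for ent in sorted(targets):
        vec = np.zeros(len(genus_names))
        for p in phyla:
            idx = [i for i, g in enumerate(genus_names) if phylum_of[g] == p]
            w = rng.lognormal(mean=0.0, sigma=1.5, size=len(idx))
            # probiotic carriers get the phylum's mean weight: present but
            # not dominant, comfortably above detection thresholds
            for j, i in enumerate(idx):
                if genus_names[i] in (PROBIOTIC_LACTO, PROBIOTIC_BIFIDO):
                    w[j] = w.mean()
            vec[idx] = w / w.sum() * targets[ent].get(p, 0.0) / 100.0
        conc[ent] = vec
    return CommunityTemplate(genus_names, phylum_of, conc)


def default_effects(
    template: CommunityTemplate,
    seed: int = 0,
    n_responders: int = 30,
    effect_log2: float = 2.0,
    sign_flip_fraction: float = 0.25,
) -> EffectModel:
    """Plant the headline response structure on a template.

    Lactobacilli expand (immediately in E2, only after the third dose in
    E1); bifidobacteria are suppressed in E2 and only transiently disturbed
    in E1.  ``n_responders`` additional genera get dose-dependent effects of
    magnitude up to ``effect_log2``; a ``sign_flip_fraction`` of them
    respond with opposite signs in the two enterotypes.  Most responses are
    transient (half-life ~2 d); a minority persist far beyond 14 d.
    """
    rng = np.random.default_rng(seed)
    eff: dict[tuple[str, str, int], float] = {}
    hl: dict[str, float] = {}

    eff[(PROBIOTIC_LACTO, "E2", 1)] = 1.5
    eff[(PROBIOTIC_LACTO, "E1", 1)] = -0.5
    eff[(PROBIOTIC_LACTO, "E1", 2)] = -0.5
    eff[(PROBIOTIC_LACTO, "E1", 3)] = 2.0
    hl[PROBIOTIC_LACTO] = 20.0
    eff[(PROBIOTIC_BIFIDO, "E2", 1)] = -1.5
    eff[(PROBIOTIC_BIFIDO, "E1", 2)] = -1.0
    eff[(PROBIOTIC_BIFIDO, "E1", 3)] = 1.5
    hl[PROBIOTIC_BIFIDO] = 30.0

    candidates = [g for g in template.genus_names if g not in (PROBIOTIC_LACTO, PROBIOTIC_BIFIDO)]
    chosen = rng.choice(candidates, size=min(n_responders, len(candidates)), replace=False)
    for g in chosen:
        sign = 1 if rng.random() < 0.5 else -1
        size = effect_log2 * rng.uniform(0.5, 1.0)
        # dose-dependent ramp in E1 (triple-dose rats), single response in E2
        eff[(g, "E1", 1)] = sign * size * 0.4
        eff[(g, "E1", 2)] = sign * size * 0.7
        eff[(g, "E1", 3)] = sign * size
        flip = -1 if rng.random() < sign_flip_fraction else 1
        eff[(g, "E2", 1)] = flip * sign * size * 0.8
        hl[g] = 50.0 if rng.random() < 0.15 else rng.uniform(1.5, 4.0)
    return EffectModel(eff, hl)


def shift_effects(
    template: CommunityTemplate,
    source: str = "E1",
    target: str = "E2",
    dose: int = 3,
    strength: float = 1.0,
    half_life_days: float = 1.0,
) -> EffectModel:
    """Effects that push the ``source`` enterotype toward the ``target`` one.

    At the given dose every genus receives ``strength x log2(p_target /
    p_source)``, so triple-dosed source rats transiently acquire the target
    composition — the planted analogue of the collective enterotype shift
    seen at 72 h.  A short half-life makes the shift recover by day 14.
    """
    ps = template.base_concentration[source]
    pt = template.base_concentration[target]
    eff = {
        (g, source, dose): float(strength * np.log2(pt[i] / ps[i]))
        for i, g in enumerate(template.genus_names)
    }
    hl = {g: half_life_days for g in template.genus_names}
    return EffectModel(eff, hl)


def _dose_times(group: str) -> list[float]:
    if group == "single":
        return [0.0]
    return [0.0, DOSE_INTERVAL_H, 2 * DOSE_INTERVAL_H]


def _cumulative_log2(
    effects: EffectModel, genus: str, enterotype: str, group: str, t_hours: float
) -> float:
    """Sum of decayed dose contributions at sampling time ``t_hours``.

    Each dose i exerts its full planted effect for the first 24 h after
    administration and decays exponentially (genus half-life) afterwards.
    """
    total = 0.0
    for i, td in enumerate(_dose_times(group), start=1):
        if t_hours <= td:
            continue
        value = effects.log2_effect.get((genus, enterotype, i), 0.0)
        if value == 0.0:
            continue
        elapsed_d = max(0.0, (t_hours - td - DOSE_INTERVAL_H)) / 24.0
        total += value * 0.5 ** (elapsed_d / effects.half_life(genus))
    return total


def simulate_cohort(
    design: SyntheticDesign,
    template: CommunityTemplate,
    effects: EffectModel,
) -> tuple[ReadCountTable, GroundTruth]:
    """Draw one cohort: one sample per rat per scheduled time point.

    A rat's baseline is a Dirichlet draw with concentration
    ``rat_overdispersion x template composition``; the composition at time t
    multiplies the baseline by ``2 ** cumulative(log2 effects, decayed)``
    and is renormalized; reads are a multinomial draw of ``design.depth``.
    Fixing ``design.seed`` fixes every emitted count.
    """
    unknown = effects.genera() - set(template.genus_names)
    if unknown:
        raise KeyError(f"effects reference genera absent from template: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(design.seed)
    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    truth_ent: dict[str, str] = {}
    genus_arr = template.genus_names
    for rat in design.rat_ids():
        ent = design.enterotype_of(rat)
        group = design.group_of_rat[rat]
        truth_ent[rat] = ent
        base = rng.dirichlet(design.rat_overdispersion * template.base_concentration[ent])
        base = np.maximum(base, 1e-12)
        for tp in design.time_points:
            t = TIME_HOURS[tp]
            mult = np.array([
                2.0 ** _cumulative_log2(effects, g, ent, group, t) for g in genus_arr
            ])
            q = base * mult
            q = q / q.sum()
            sid = f"{rat}_{tp}"
            counts[sid] = rng.multinomial(design.depth, q)
            meta_rows.append((sid, rat, group, tp, "fecal", tp == "0h", ent))
    count_df = pd.DataFrame.from_dict(counts, orient="index", columns=genus_arr).astype(np.int64)
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "rat_id", "group", "time_point", "environment", "is_control", "known_enterotype"],
    ).set_index("sample_id")
    meta.index.name = None
    return ReadCountTable(count_df, meta), GroundTruth(truth_ent, effects)


def export_ground_truth(gt: GroundTruth, path) -> None:
    """Write ground truth as a single TSV (lossless round trip).

    Rows are typed: ``enterotype`` rows carry (rat_id, enterotype), ``effect``
    rows carry (genus, enterotype, dose_index, log2_effect, half_life_days).
    """
    with open(path, "w") as fh:
        fh.write("record_type\tkey\tenterotype\tdose_index\tlog2_effect\thalf_life_days\n")
        for rat in sorted(gt.enterotype_of_rat):
            fh.write(f"enterotype\t{rat}\t{gt.enterotype_of_rat[rat]}\t\t\t\n")
        for _, r in gt.effect_rows().iterrows():
            fh.write(
                f"effect\t{r['genus']}\t{r['enterotype']}\t{int(r['dose_index'])}"
                f"\t{r['log2_effect']!r}\t{r['half_life_days']!r}\n"
            )


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    ents = {
        r["key"]: r["enterotype"]
        for _, r in df[df["record_type"] == "enterotype"].iterrows()
    }
    eff: dict[tuple[str, str, int], float] = {}
    hl: dict[str, float] = {}
    for _, r in df[df["record_type"] == "effect"].iterrows():
        eff[(r["key"], r["enterotype"], int(r["dose_index"]))] = float(r["log2_effect"])
        hl[r["key"]] = float(r["half_life_days"])
    return GroundTruth(ents, EffectModel(eff, hl))


def write_cohort(table: ReadCountTable, counts_path, metadata_path) -> None:
    """Wide TSV count table + TSV metadata with deterministic column order."""
    out = table.counts.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(counts_path, sep="\t", index=False)
    meta = table.metadata.copy()
    meta.insert(0, "sample_id", meta.index)
    meta.to_csv(metadata_path, sep="\t", index=False)


def load_config(path_or_stream) -> tuple[SyntheticDesign, CommunityTemplate, EffectModel]:
    """Build design/template/effects from a YAML config.

    Recognized keys (all optional, with study defaults):

    .. code-block:: yaml

        design:   {depth: 30000, rat_overdispersion: 200, seed: 0}
        template: {n_genera: 220, seed: 0, phylum_targets: {...}}
        effects:  {n_responders: 30, effect_log2: 2.0, seed: 0}
    """
    if hasattr(path_or_stream, "read"):
        cfg = yaml.safe_load(path_or_stream) or {}
    else:
        with open(path_or_stream) as fh:
            cfg = yaml.safe_load(fh) or {}
    d = cfg.get("design", {})
    design = SyntheticDesign.default(
        seed=int(d.get("seed", 0)),
        depth=int(d.get("depth", 30000)),
        rat_overdispersion=float(d.get("rat_overdispersion", 200.0)),
    )
    if "time_points" in d:
        design.time_points = tuple(d["time_points"])
    t = cfg.get("template", {})
    template = build_template(
        n_genera=int(t.get("n_genera", 220)),
        phylum_targets=t.get("phylum_targets"),
        seed=int(t.get("seed", d.get("seed", 0))),
    )
    e = cfg.get("effects", {})
    effects = default_effects(
        template,
        seed=int(e.get("seed", d.get("seed", 0))),
        n_responders=int(e.get("n_responders", 30)),
        effect_log2=float(e.get("effect_log2", 2.0)),
        sign_flip_fraction=float(e.get("sign_flip_fraction", 0.25)),
    )
    return design, template, effects
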