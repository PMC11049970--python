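"""End-to-end orchestration: simulate/load -> panel -> enterotype ->
stability -> differential -> diversity -> selection -> report.

Every tabular output is written with a header comment carrying the tool
version, the config hash and the seed, and all randomness flows from the
single config seed, so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import differential as da
from . import diversity as dv
from . import enterotypes as et
from .abundance import (
    ReadCountTable,
    percentages,
    phylum_summary,
    read_counts,
    read_phylum_map,
    select_marker_panel,
)
from .synthetic import SyntheticDesign, build_template, default_effects, load_config, simulate_cohort, write_cohort, export_ground_truth

__all__ = ["RunConfig", "RunReport", "run_pipeline", "shift_table"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Leave ``counts_path``/``metadata_path`` unset to simulate a synthetic
    cohort (optionally from ``sim_config_path``).
    """

    out_dir: str = "enteroshift_run"
    counts_path: str | None = None
    metadata_path: str | None = None
    phylum_map_path: str | None = None
    sim_config_path: str | None = None
    marker_threshold: float = 0.01
    silhouette_threshold: float = 0.1
    p_strong: float = 0.001
    p_significant: float = 0.05
    min_pairs: int = 3
    min_percent: float = 0.01
    fold_bound: float = 2.0
    selection_rounds: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("marker_threshold", "silhouette_threshold", "min_percent", "fold_bound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_strong", "p_significant"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for p in (self.counts_path, self.metadata_path, self.sim_config_path, self.phylum_map_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if (self.counts_path is None) != (self.metadata_path is None):
            raise ValueError("counts_path and metadata_path must be given together")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config: RunConfig
    stage_summaries: dict = field(default_factory=dict)
    calls: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "version": __version__,
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
            "stages": self.stage_summaries,
            "calls": self.calls,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (
        f"# enteroshift v{__version__} seed={config.seed} config={config.config_hash()}\n"
    )
    body = df.to_csv(sep="\t", index=True)
    path.write_text(header + body)


def shift_table(calls_by_timepoint: Mapping[str, Mapping[str, et.EnterotypeCall]], metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-rat enterotype trajectory with shift flags.

    ``calls_by_timepoint`` maps time-point label -> {sample -> call}.  A
    sample is flagged ``flipped`` when its decision differs from its rat's
    control decision, and ``unstable`` when no majority emerged; the two are
    kept distinct.
    """
    if len(calls_by_timepoint) < 2:
        raise ValueError("need calls for at least two time points")
    tps = list(calls_by_timepoint)
    rows = []
    rats = sorted(metadata["rat_id"].unique())
    for rat in rats:
        row: dict = {"rat_id": rat}
        control_decision = None
        for tp in tps:
            decision = None
            for sid, call in calls_by_timepoint[tp].items():
                if sid in metadata.index and metadata.loc[sid, "rat_id"] == rat:
                    decision = call.decision
                    break
            row[tp] = decision
            if tp == tps[0]:
                control_decision = decision
        flips = [
            tp for tp in tps[1:]
            if row[tp] not in (None, "unstable") and control_decision not in (None, "unstable")
            and row[tp] != control_decision
        ]
        row["flipped_at"] = ",".join(flips)
        row["n_unstable"] = sum(1 for tp in tps if row[tp] == "unstable")
        rows.append(row)
    return pd.DataFrame(rows).set_index("rat_id")


def _acquire_table(config: RunConfig, out: Path) -> ReadCountTable:
    if config.counts_path is not None:
        return read_counts(config.counts_path, config.metadata_path)
    if config.sim_config_path is not None:
        design, template, effects = load_config(config.sim_config_path)
        design.seed = config.seed
    else:
        design = SyntheticDesign.default(seed=config.seed)
        template = build_template(seed=config.seed)
        effects = default_effects(template, seed=config.seed)
    table, truth = simulate_cohort(design, template, effects)
    write_cohort(table, out / "counts.tsv", out / "metadata.tsv")
    export_ground_truth(truth, out / "ground_truth.tsv")
    return table


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order and write the artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config)
    t0 = time.time()

    table = _acquire_table(config, out)
    report.stage_summaries["input"] = {
        "n_samples": len(table.sample_ids),
        "n_genera": len(table.genus_ids),
    }

    panel = select_marker_panel(table, config.marker_threshold)
    pd.DataFrame({"genus": list(panel)}).to_csv(out / "panel.tsv", sep="\t", index=False)
    report.stage_summaries["panel"] = {"size": len(panel), "threshold": config.marker_threshold}

    ab = percentages(table, panel, pseudocount=0)
    fecal = table.metadata[table.metadata["environment"] == "fecal"]
    controls = fecal[fecal["is_control"]].index.tolist()
    ab_controls = ab.subset(controls)
    dm = et.jsd_distance(ab_controls)
    _write_tsv(dm.to_frame(), out / "control_distances.tsv", config)

    scan = et.ch_scan(dm, range(2, min(6, len(controls) - 1)), seed=config.seed)
    part = et.pam(dm, 2, seed=config.seed)
    sizes = {c: len(part.members(c)) for c in part.medoids}
    bigger = max(sizes, key=lambda c: (sizes[c], -c))
    reference = {s: ("E1" if part.labels[s] == bigger else "E2") for s in part.labels}
    report.stage_summaries["enterotyping"] = {
        "ch_index": {str(k): v for k, v in scan.ch_index.items()},
        "optimal_k": scan.optimal_k,
        "n_E1": sum(1 for v in reference.values() if v == "E1"),
        "n_E2": sum(1 for v in reference.values() if v == "E2"),
    }

    if config.phylum_map_path is not None:
        phyla = read_phylum_map(config.phylum_map_path)
        _write_tsv(phylum_summary(ab, phyla), out / "phylum_summary.tsv", config)

    # stability grid over control set + each later time point set
    tps = [tp for tp in pd.unique(fecal["time_point"]) if tp != "0h"]
    ab_sets = {"con": ab_controls}
    for tp in tps:
        ids = fecal[(fecal["time_point"] == tp)].index.tolist()
        if ids:
            ab_sets[tp] = ab.subset(ids)
    grid = et.stability_grid(
        ab_sets, reference, threshold=config.silhouette_threshold, seed=config.seed
    )
    _write_tsv(grid.to_heatmap_frame(), out / "silhouette_grid.tsv", config)

    calls: dict[str, et.EnterotypeCall] = {}
    for sid in grid.S.columns:
        calls[sid] = et.call_enterotype(grid, sid)
    report.calls = {
        sid: {"decision": c.decision, "votes": c.votes} for sid, c in sorted(calls.items())
    }
    calls_by_tp: dict[str, dict[str, et.EnterotypeCall]] = {}
    for sid, call in calls.items():
        tp = fecal.loc[sid, "time_point"] if sid in fecal.index else None
        if tp is not None:
            calls_by_tp.setdefault(tp, {})[sid] = call
    if len(calls_by_tp) >= 2:
        ordered = {tp: calls_by_tp[tp] for tp in ("0h", *tps) if tp in calls_by_tp}
        shifts = shift_table(ordered, fecal)
        _write_tsv(shifts, out / "shift_table.tsv", config)
        report.stage_summaries["shifts"] = {
            "n_flipped": int((shifts["flipped_at"] != "").sum()),
            "n_with_unstable": int((shifts["n_unstable"] > 0).sum()),
        }

    # paired differential response per enterotype (dosing scheme)
    ab1 = percentages(table, panel, pseudocount=1)
    meta_ref = fecal.copy()
    meta_ref["known_enterotype"] = [
        reference.get(f"{r}_0h", meta_ref.loc[s].get("known_enterotype", ""))
        for s, r in zip(meta_ref.index, meta_ref["rat_id"])
    ]
    pairsets = da.build_pairs(meta_ref, "dosing")
    all_results: dict[str, list[da.DifferentialResult]] = {}
    for ps in pairsets:
        if len(ps) < config.min_pairs:
            continue
        res = da.differential_table(
            ab1, ps, panel, min_percent=config.min_percent, min_pairs=config.min_pairs
        )
        if res:
            all_results[f"{ps.enterotype}:{ps.group_label}"] = res
    volcano_frames = [da.volcano_table(res) for res in all_results.values() if res]
    if volcano_frames:
        volcano = pd.concat(volcano_frames, ignore_index=True)
        _write_tsv(volcano.set_index("genus"), out / "volcano.tsv", config)
        report.stage_summaries["differential"] = {
            "n_groups": len(all_results),
            "n_strong": int((volcano["tier"] == "strong").sum()),
            "n_significant": int((volcano["tier"] == "significant").sum()),
        }

    divs = dv.diversity_table(table)
    div_df = pd.DataFrame(
        [(d.sample_id, d.shannon, d.n_taxa) for d in divs],
        columns=["sample_id", "shannon_H", "n_taxa"],
    ).set_index("sample_id")
    _write_tsv(div_df, out / "diversity.tsv", config)
    report.stage_summaries["diversity"] = {
        "mean_H": float(div_df["shannon_H"].mean()),
        "mean_taxa": float(div_df["n_taxa"].mean()),
    }

    # representative-taxon selection on one E1 and one E2 trajectory
    by_label: dict[str, list[da.DifferentialResult]] = {}
    for key, res in all_results.items():
        by_label.setdefault(key.split(":", 1)[1], []).extend(res)
    pool = dv.candidate_pool(by_label, min_fold=config.fold_bound, alpha=config.p_significant)
    profile_order = _selection_profiles(meta_ref, reference)
    if pool and profile_order:
        rounds = min(config.selection_rounds, len(pool) // len(profile_order))
        if rounds >= 1:
            sel = dv.select_representatives(pool, ab, profile_order, rounds=rounds)
            sel = dv.remove_dominants(sel, profile_order[:2])
            sector = dv.normalizing_sector(sel)
            sel_df = sel.percent[sel.taxa].T
            sel_df.loc["N"] = sector
            _write_tsv(sel_df, out / "selection.tsv", config)
            report.stage_summaries["selection"] = {
                "pool": len(pool),
                "selected": len(sel.taxa),
                "removed": sel.removed_dominants,
            }

    report.stage_summaries["timing_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(report.to_json())
    return report


def _selection_profiles(fecal: pd.DataFrame, reference: Mapping[str, str]) -> list[str]:
    """Interleaved E1/E2 trajectory of one rat each across time points."""
    def _rat_for(ent: str) -> str | None:
        for sid, lab in sorted(reference.items()):
            if lab == ent:
                return fecal.loc[sid, "rat_id"] if sid in fecal.index else None
        return None

    r1, r2 = _rat_for("E1"), _rat_for("E2")
    if r1 is None or r2 is None:
        return []
    tps = [tp for tp in ("0h", "24h", "48h", "72h", "14d") if (fecal["time_point"] == tp).any()]
    order = []
    for tp in tps:
        for rat in (r1, r2):
            hits = fecal[(fecal["rat_id"] == rat) & (fecal["time_point"] == tp)]
            if len(hits):
                order.append(hits.index[0])
    return order
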