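"""Config-driven end-to-end orchestration.

Runs simulate -> balance/insulate -> call boundaries -> classify ->
differential peaks -> enrichments -> expression association -> pileups,
writing a machine-readable report (JSON summary + TSV tables). Every
stochastic stage draws its stream from the single config seed through
fixed offsets, so a config re-run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import diffbind, domains, integrate, pileup, synth
from .contacts import balance, insulation_track
from .domains import BoundaryClassTable, BoundarySet
from .io_model import FeatureSet

__all__ = [
    "RunConfig",
    "run_differential_architecture",
    "summarize_partitions",
    "match_recovery",
]


@dataclasses.dataclass
class RunConfig:
    """Pipeline parameters; defaults reproduce the standard synthetic run."""

    seed: int = 0
    outdir: str | None = None
    chrom_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(synth.DEFAULT_GENOME.chrom_sizes)
    )
    resolution: int = 10_000
    coarse_window: int = 100_000
    fine_window: int = 50_000
    tad_prominence: float = 2.5
    subtad_prominence: float = 0.5
    boundary_tol: int = 10_000
    peak_gene_tol: int = 3_000
    fdr_max: float = 0.01
    logfc_min: float = 1.0
    n_perm: int = 199
    pileup_flank: int = 200_000
    contact: synth.ContactParams = dataclasses.field(default_factory=synth.ContactParams)
    perturb: synth.PerturbParams = dataclasses.field(default_factory=synth.PerturbParams)
    features: synth.FeatureParams = dataclasses.field(default_factory=synth.FeatureParams)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = RunConfig()
        known = {f.name for f in dataclasses.fields(RunConfig)}
        for key, val in raw.items():
            if key not in known:
                raise ValueError(f"unknown config field {key!r}")
            if key in {"contact", "perturb", "features"}:
                cls = {"contact": synth.ContactParams, "perturb": synth.PerturbParams,
                       "features": synth.FeatureParams}[key]
                val = cls(**val)
            setattr(cfg, key, val)
        return cfg


def summarize_partitions(table: BoundaryClassTable) -> dict[str, Any]:
    """Boundary class counts and gain/loss percentages.

    Percentages use the control boundary count as denominator (the reading
    under which 810 gained of 11,580 control boundaries is a 7% gain).
    Full precision is kept; a rounded integer percent is reported alongside.
    """
    counts = table.counts()
    control_total = int((table.df["source"] == "control").sum())
    if control_total == 0:
        raise ValueError("zero control boundaries")
    lost = counts.get("lost", 0)
    gained = counts.get("gained", 0)
    return {
        "counts": {k: int(counts.get(k, 0)) for k in ("constant", "lost", "gained", "discordant")},
        "control_total": control_total,
        "lost_pct": 100.0 * lost / control_total,
        "gained_pct": 100.0 * gained / control_total,
        "lost_pct_rounded": round(100.0 * lost / control_total),
        "gained_pct_rounded": round(100.0 * gained / control_total),
    }


def match_recovery(
    truth_bins: dict[str, np.ndarray],
    called_pos: dict[str, np.ndarray],
    resolution: int,
    tol_bins: int = 1,
) -> dict[str, float]:
    """Recall / precision / F1 of called positions against truth bins."""
    tp = fn = 0
    called_used = 0
    total_called = sum(len(v) for v in called_pos.values())
    for chrom, bins in truth_bins.items():
        truth_bp = np.asarray(bins) * resolution
        called = np.asarray(called_pos.get(chrom, np.array([])), dtype=np.int64)
        for t in truth_bp.tolist():
            if called.size and np.abs(called - t).min() <= tol_bins * resolution:
                tp += 1
            else:
                fn += 1
        if truth_bp.size and called.size:
            called_used += int(
                (np.abs(called[:, None] - truth_bp[None, :]).min(axis=1) <= tol_bins * resolution).sum()
            )
    recall = tp / (tp + fn) if tp + fn else np.nan
    precision = called_used / total_called if total_called else np.nan
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall and np.isfinite(precision + recall)
        else 0.0
    )
    return {"recall": recall, "precision": precision, "f1": f1, "n_truth": tp + fn, "n_called": total_called}


def _genome_boundary_set(level: str, per_chrom: dict[str, domains.CalledHierarchy],
                         resolution: int, chrom_sizes: dict[str, int]) -> BoundarySet:
    dfs = []
    for chrom, called in per_chrom.items():
        bs = called.tad if level == "TAD" else called.subtad
        dfs.append(bs.df)
    df = pd.concat(dfs, ignore_index=True) if dfs else pd.DataFrame(columns=["chrom", "bin", "pos", "strength"])
    return BoundarySet(level, resolution, df, dict(chrom_sizes))


def run_differential_architecture(config: RunConfig) -> dict[str, Any]:
    """Execute the full synthetic differential-architecture analysis.

    Returns the report dict; when ``config.outdir`` is set, also writes
    summary.json plus the backing TSV tables.
    """
    exp = synth.simulate_experiment(
        genome=synth.GenomeSpec(dict(config.chrom_sizes), config.resolution),
        contact_params=config.contact,
        perturb_params=config.perturb,
        feature_params=config.features,
        seed=config.seed,
    )
    report: dict[str, Any] = {"schema_version": 1, "seed": config.seed}

    called = {"control": {}, "clone1": {}, "clone2": {}}
    tracks = {"control": {}, "clone1": {}, "clone2": {}}
    for chrom in exp.genome.chrom_sizes:
        for cond, mats in (
            ("control", exp.control_matrices),
            ("clone1", exp.clone1_matrices),
            ("clone2", exp.clone2_matrices),
        ):
            bal = balance(mats[chrom])
            tracks[cond][chrom] = insulation_track(bal, config.fine_window)
            called[cond][chrom] = domains.call_hierarchy(
                bal,
                config.coarse_window,
                config.fine_window,
                (config.tad_prominence, config.subtad_prominence),
                balanced=True,
            )

    class_tables: dict[str, BoundaryClassTable] = {}
    for level in ("TAD", "subTAD"):
        sets = {
            cond: _genome_boundary_set(level, called[cond], config.resolution, exp.genome.chrom_sizes)
            for cond in ("control", "clone1", "clone2")
        }
        table = domains.classify_boundaries(
            sets["control"], sets["clone1"], sets["clone2"], tol=config.boundary_tol
        )
        class_tables[level] = table
        report[f"{level}_partition"] = summarize_partitions(table)

    # truth recovery of removed subTAD boundaries
    lost_pos = {
        c: class_tables["subTAD"].positions("lost", c) for c in exp.genome.chrom_sizes
    }
    report["lost_subtad_recovery"] = match_recovery(
        exp.record.removed_subtad, lost_pos, config.resolution, tol_bins=1
    )

    # differential CTCF peaks
    thresholds = diffbind.DiffThresholds(config.fdr_max, config.logfc_min)
    ctcf = diffbind.classify_differential(exp.features.ctcf_table, thresholds)
    report["ctcf_classes"] = ctcf["class"].value_counts().to_dict()
    truth_lost = ctcf["truth_class"] == "lost"
    called_lost = ctcf["class"] == "lost"
    report["ctcf_lost_sensitivity"] = (
        float((truth_lost & called_lost).sum() / truth_lost.sum()) if truth_lost.sum() else np.nan
    )

    # O/E enrichment of lost CTCF at lost subTAD boundaries
    lost_sites = FeatureSet(
        iv for iv, cls in zip(exp.features.ctcf_peaks.intervals, ctcf["class"]) if cls == "lost"
    )
    if len(lost_sites) and (class_tables["subTAD"].df["class"] == "lost").any():
        enr = integrate.oe_boundary_enrichment(
            lost_sites,
            class_tables["subTAD"],
            tol=config.boundary_tol,
            n_perm=config.n_perm,
            seed=config.seed + 100,
            boundary_class="lost",
        )
        report["lost_ctcf_at_lost_subtad"] = dataclasses.asdict(enr)

    # boundary-expression association
    assoc = integrate.boundary_expression_association(
        class_tables["subTAD"], exp.features.expression, tol=config.boundary_tol
    )
    report["subtad_expression_association"] = assoc.to_dict(orient="records")

    # pileups at truth-lost CTCF anchors, control vs clone1 (first chromosome)
    chrom0 = next(iter(exp.genome.chrom_sizes))
    anchors = exp.features.ctcf_peaks.subset(
        [(iv.chrom == chrom0) and (tc == "lost")
         for iv, tc in zip(exp.features.ctcf_peaks.intervals, exp.features.ctcf_table["truth_class"])]
    )
    pile = {}
    if len(anchors):
        for cond, mats in (("control", exp.control_matrices), ("clone1", exp.clone1_matrices)):
            res = pileup.anchor_pileup(
                balance(mats[chrom0]), anchors, flank=config.pileup_flank,
                n_random_sets=5, seed=config.seed + 200,
            )
            pile[cond] = res
            report[f"pileup_{cond}_quadrants"] = res.quadrant_means()

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for level, table in class_tables.items():
            table.df.to_csv(out / f"boundaries_{level}.tsv", sep="\t", index=False)
        ctcf.to_csv(out / "ctcf_differential.tsv", sep="\t", index=False)
        assoc.to_csv(out / "subtad_expression_association.tsv", sep="\t", index=False)
        exp.features.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
        for cond, res in pile.items():
            np.savetxt(out / f"pileup_{cond}.txt", res.matrix)
        (out / "summary.json").write_text(json.dumps(report, indent=2, default=float))
    return report
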