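"""Couple boundary changes to CTCF loss, chromatin marks and expression.

Computes O/E colocalization enrichments of differential CTCF/mark sites at
classified boundaries, the gained-next-to-lost boundary adjacency test, the
boundary-class expression association, and the delta-delta correlation of
mark changes with expression changes.
"""

import json
from pathlib import Path

import pandas as pd

from subtadscope import diffbind, domains, integrate, synth
from subtadscope.pipeline import RunConfig, run_differential_architecture
from subtadscope.io_model import FeatureSet

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    exp = synth.simulate_experiment(seed=SEED)
    summary = {}

    # classified boundaries from the pipeline (reuses the same seed/config)
    import subtadscope.pipeline as pl
    from subtadscope.contacts import balance

    cfg = RunConfig(seed=SEED)
    report = run_differential_architecture(cfg)

    # truth-level subTAD class table for the association statistics
    rows = []
    for c in exp.genome.chrom_sizes:
        for p in (exp.record.removed_subtad[c] * exp.genome.resolution).tolist():
            rows.append(dict(chrom=c, pos=p, partner1=None, partner2=None,
                             source="control", **{"class": "lost"}))
        for p in (exp.record.added_subtad[c] * exp.genome.resolution).tolist():
            rows.append(dict(chrom=c, pos=p, partner1=None, partner2=None,
                             source="clones", **{"class": "gained"}))
    table = domains.BoundaryClassTable(
        "subTAD", exp.genome.resolution, pd.DataFrame(rows), dict(exp.genome.chrom_sizes)
    )

    adj = domains.gained_lost_adjacency(table, n_random=999, seed=SEED)
    summary["gained_next_to_lost"] = adj

    ctcf = diffbind.classify_differential(exp.features.ctcf_table, diffbind.CTCF_THRESHOLDS)
    lost_sites = FeatureSet(
        iv for iv, cls in zip(exp.features.ctcf_peaks.intervals, ctcf["class"]) if cls == "lost"
    )
    enr = integrate.oe_boundary_enrichment(
        lost_sites, table, tol=10_000, n_perm=999, seed=SEED, boundary_class="lost"
    )
    summary["lost_ctcf_at_lost_subtad_oe"] = enr.__dict__

    marks = diffbind.classify_differential(exp.features.mark_table, diffbind.MARK_THRESHOLDS)
    gained_marks = FeatureSet(
        iv for iv, cls in zip(exp.features.mark_sites.intervals, marks["class"]) if cls == "gained"
    )
    if len(gained_marks):
        enr2 = integrate.oe_boundary_enrichment(
            gained_marks, table, tol=10_000, n_perm=999, seed=SEED + 1, boundary_class="gained"
        )
        summary["gained_mark_at_gained_subtad_oe"] = enr2.__dict__

    assoc = integrate.boundary_expression_association(table, exp.features.expression, tol=10_000)
    assoc.to_csv(OUT / "04_boundary_expression.tsv", sep="\t", index=False)
    summary["boundary_expression"] = assoc.to_dict(orient="records")

    fdf = pd.DataFrame(dict(chrom=marks["chrom"], pos=marks["pos"], logfc=marks["logfc"]))
    r, p, n = integrate.delta_delta_correlation(fdf, exp.features.expression, tol=3_000)
    summary["mark_expression_delta_delta"] = {"r": r, "p": p, "n_pairs": n}

    (OUT / "04_integration_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    print(json.dumps(summary, indent=2, default=float))


if __name__ == "__main__":
    main()
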