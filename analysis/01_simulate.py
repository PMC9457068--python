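"""Generate the paired-condition synthetic experiment used by all later steps.

Simulates a control line and two clones sharing one boundary perturbation on
the standard two-chromosome 2 x 20 Mb genome at 10-kb bins, then writes the
raw data (contact matrices, peaks, densities, expression, ground truth) under
scratch/synthetic/ and a compact summary of what was implanted under
results/.
"""

import json
from pathlib import Path

from subtadscope import io_model, synth

SEED = 1
OUT_RAW = Path("scratch/synthetic")
OUT = Path("results")


def main() -> None:
    OUT_RAW.mkdir(parents=True, exist_ok=True)
    OUT.mkdir(exist_ok=True)
    exp = synth.simulate_experiment(seed=SEED)

    with open(OUT_RAW / "chrom.sizes", "w") as fh:
        for c, s in exp.genome.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    for cond, mats in (("control", exp.control_matrices),
                       ("clone1", exp.clone1_matrices), ("clone2", exp.clone2_matrices)):
        for chrom, m in mats.items():
            io_model.write_contact_matrix(m, OUT_RAW / f"{cond}_{chrom}.triplet.txt")
    io_model.write_feature_set(exp.features.ctcf_peaks, OUT_RAW / "ctcf_peaks.bed")
    io_model.write_feature_set(exp.features.mark_sites, OUT_RAW / "mark_sites.bed")
    exp.features.ctcf_table.to_csv(OUT_RAW / "ctcf_densities.tsv", sep="\t", index=False)
    exp.features.mark_table.to_csv(OUT_RAW / "mark_densities.tsv", sep="\t", index=False)
    exp.features.expression.to_csv(OUT_RAW / "expression.tsv", sep="\t", index=False)

    summary = {
        "seed": SEED,
        "genome": exp.genome.chrom_sizes,
        "resolution": exp.genome.resolution,
        "n_tad_boundaries": {c: int(len(v)) for c, v in exp.control.tad_boundaries.items()},
        "n_subtad_boundaries": {c: int(len(v)) for c, v in exp.control.subtad_boundaries.items()},
        "removed_subtad": {c: int(len(v)) for c, v in exp.record.removed_subtad.items()},
        "added_subtad": {c: int(len(v)) for c, v in exp.record.added_subtad.items()},
        "removed_tad": {c: int(len(v)) for c, v in exp.record.removed_tad.items()},
        "added_tad": {c: int(len(v)) for c, v in exp.record.added_tad.items()},
        "n_ctcf_peaks": int(len(exp.features.ctcf_table)),
        "n_mark_sites": int(len(exp.features.mark_table)),
        "n_genes": int(len(exp.features.expression)),
    }
    (OUT / "01_simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print("simulated paired-condition experiment:")
    print(json.dumps(summary, indent=2))
    print(f"raw data under {OUT_RAW}/")


if __name__ == "__main__":
    main()
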