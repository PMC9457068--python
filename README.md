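# subtadscope

Differential analysis of nested chromatin-domain architecture from binned
Hi-C contact matrices, with the peak and expression integration needed to
interpret boundary turnover.

Genomes partition into topologically associating domains (TADs, 100 kb –
1 Mb) with smaller self-interacting subTADs nested inside them. When the
insulator protein CTCF is depleted — as under the CTCF copy-number loss
common in breast tumours — the subTAD level reorganises much more than the
TAD level, and the boundaries that appear or disappear couple to chromatin
marks (H3K27ac, H3K4me3) and transcription. `subtadscope` implements that
entire analysis as a tested pipeline:

- **contacts** — ICE-style matrix balancing, distance-decay expected
  profiles, diamond insulation scores `S(i) = Σ contacts crossing bin i in a
  ±w window`, reported as `log2(S(i) / mean S)`, and obs/exp
  Pearson correlation between samples;
- **domains** — two-scale boundary calling (local insulation minima with a
  prominence threshold per level) and cross-condition classification of
  boundaries into constant / lost / gained / discordant by optimal
  one-to-one matching within ±10 kb across a control and two clones;
- **diffbind** — differential peak occupancy (pooled-variance z-test on
  log2 densities, Benjamini–Hochberg FDR; lost/gained at FDR < 0.01 and
  |logFC| > 1 for CTCF-style calls), genomic-context annotation and TSS
  metaprofiles;
- **integrate** — observed/expected colocalization enrichment with
  permutation nulls, gene-set enrichment against equinumerous constant-site
  subsets, boundary-class expression association, delta–delta
  (mark-change vs expression-change) correlation, and per-gene correlation
  ranking against a reference gene;
- **pileup** — aggregate obs/exp windows around anchors and anchor pairs,
  and average insulation profiles per condition;
- **synth** — a paired-condition synthetic-genome generator (nested
  domains, distance-decay Poisson contacts, boundary perturbation, coupled
  peaks/marks/expression) with machine-readable ground truth;
- **pipeline / cli** — config-driven orchestration (`subtadscope run`) and
  thin subcommands (`validate`, `simulate`, `insulation`, `call-domains`).

The numbered scripts under `analysis/` run the full study on the standard
synthetic genome: `01_simulate.py` → `02_boundaries.py` →
`03_differential_binding.py` → `04_integration.py` → `05_pileups.py`,
writing compact tables under `results/` (bulky raw data under `scratch/`).

## Worked example

```sh
python analysis/02_boundaries.py
```

calls and classifies boundaries across the simulated control and two
perturbed clones (2 × 20 Mb genome, 10-kb bins) and prints:

```
TAD: 70 control boundaries; 9% lost, 10% gained
subTAD: 132 control boundaries; 19% lost, 8% gained
implanted subTAD removals recovered with recall 0.91, precision 0.84, F1 0.87
```

Reading: the control genome carried 70 TAD and 132 subTAD boundaries; after
perturbation (which removed 17% of subTAD and 10% of TAD boundaries and
added 11% / 7%), the caller+classifier recovers the implanted subTAD
removal set with F1 0.87 at ±1 bin. The same run writes the per-boundary
class tables, the differential-CTCF table and the boundary–expression
association under `scratch/analysis/pipeline/`; gained subTAD boundaries
carry a mean expression log2FC close to the implanted +1, and lost CTCF
sites are ~25-fold enriched (O/E) at lost subTAD boundaries.

The same pipeline runs from a YAML config on the command line:

```sh
subtadscope run --config run.yaml --outdir out --seed 1
```

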