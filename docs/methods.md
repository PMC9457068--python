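# Methods

`subtadscope` analyses condition-specific reorganisation of nested chromatin
domains — topologically associating domains (TADs) and the smaller
self-interacting domains nested inside them (subTADs) — from binned Hi-C
contact matrices, together with the chromatin-mark and expression changes
that accompany boundary turnover. The motivating biology is CTCF copy-number
loss in mammary epithelial cells, where the subTAD level reorganises far more
than the TAD level and gained subTAD boundaries couple to transcriptional
up-regulation; the package reproduces that analysis workflow on synthetic
genomes with known ground truth.

## Contact model and balancing

A contact matrix is symmetric, non-negative, per chromosome at a fixed bin
size (10 kb throughout the standard analyses). Matrix balancing equalises
valid-bin row sums by iterative proportional fitting; the update divides by
the outer product of the *square roots* of the normalised row sums, the
damped symmetric form of the classical algorithm. Undamped division
oscillates on strongly diagonal-dominant matrices like these; the damped
update converges in under ten rounds to a relative row-sum deviation of
1e-3 (the default tolerance). Zero-sum rows are masked and excluded from all
downstream statistics. All analyses are cis-only: trans contacts never enter
the model.

The expected profile is the mean balanced contact per bin separation, and
observed/expected (O/E) maps divide each pixel by the expectation at its
separation.

## Insulation score and boundary calling

For bin *i* and window *w* bins, the raw insulation is the sum of contacts
between the *w* bins left of *i* and the *w* bins right of *i* (the square
"diamond" crossing bin *i*). The reported score is log2 of the ratio to the
chromosome-mean raw insulation; it is undefined within *w* bins of an edge
and at masked bins. Two properties make this usable as a boundary statistic:
a boundary retaining a fraction *f* of cross-boundary contacts depresses the
score by roughly |log2 f|, and the score is invariant to global scaling of
the matrix.

Boundaries are local minima of the insulation score with topographic
prominence at least a threshold, computed per contiguous finite segment of
the track (prominence never leaks across gaps). The hierarchy is called at
two scales: a coarse window (100 kb) for TAD boundaries and a fine window
(50 kb) for subTAD candidates, where subTAD boundaries are fine-window
minima not within one bin of a TAD boundary.

The prominence defaults are 2.5 (TAD) and 0.5 (subTAD), in log2 units. The
separation between levels comes from boundary *strength*, not window size:
with a realistic contact model, an insulation dip of depth ~|log2 f| appears
at both windows, so a low TAD-level threshold would swallow strong subTAD
boundaries into the TAD set. On the synthetic genomes the two strength
distributions are bimodal (TAD dips >= ~3, subTAD dips ~0.5–1.8, Poisson
noise minima <= ~0.35) and the defaults sit in the gaps; both are exposed as
parameters for data with different strength profiles.

## Cross-condition boundary classification

Boundary sets from a control and two perturbed clones are matched
one-to-one within a tolerance (±10 kb by default) by optimal assignment:
the matching maximises the number of matched pairs, then minimises the
total matched distance, with deterministic tie-breaking. A control boundary
matched in both clones is *constant*, in neither *lost*, in exactly one
*discordant*. Clone boundaries unmatched in the control are *gained* when
mutually matched between the clones and *discordant* otherwise — the
"present in both clones" requirement is applied symmetrically to gains and
losses, so one-clone events never inflate either class. Partition
percentages use the control boundary count as denominator.

The gained-next-to-lost adjacency test takes the median distance from each
gained boundary to the nearest lost boundary and compares it to the same
statistic under uniform re-placement of the gained set (per-chromosome
counts preserved); the empirical p uses the (1+k)/(n+1) convention and can
never be zero.

## Differential occupancy

Peaks are quantified per replicate as library-size-normalised mean signal
over the peak interval. The differential test is a z-test on log2(density+1)
whose variance is pooled across all peaks and both conditions — at two
replicates per condition a per-peak variance is hopeless, while the pooled
estimate is stable and yields calibrated p-values when the log-density noise
is homoscedastic, which the generator (and, approximately, deep ChIP-seq)
satisfies. Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest` and cross-checked against the textbook step-up
formula in the test suite. Classes follow the fold-change/FDR conventions of
the motivating study: CTCF-style calls use FDR < 0.01 with |logFC| > 1
(strict inequalities); histone-mark calls use FDR <= 0.05 with |logFC| >= 1
(inclusive). The pseudo-count of 1 in the logFC guards zero densities; as a
consequence exact scale invariance of logFC holds only well above the
pseudo-count.

Genomic context annotation is a three-way precedence partition — promoter
(within ±3 kb of a TSS), gene body, distal intergenic — and TSS metaprofiles
average strand-oriented signal windows across a gene subset.

## Colocalization and coupling statistics

O/E boundary enrichment counts features within ±tol of any boundary and
compares to uniform re-placement of the features (n_perm permutations,
sub-seeded deterministically). One-sided and two-sided (smaller tail
doubled, capped at 1) empirical p-values are reported.

Gene-set enrichment of a query peak set maps sites to genes within ±3 kb of
the TSS and compares the query's gene-hit count per set against 100
equinumerous random subsets of the constant-site pool (mean ± SEM, empirical
p); permutation streams are independent across gene sets by sub-seeding.

Boundary–expression association assigns a gene to a boundary class when its
TSS lies within ±10 kb of a boundary of that class (a gene may sit in
several classes) and reports the class mean log2FC, SEM and a two-sided
rank-sum p against all genes. Delta-delta correlation pairs each gene with
its *nearest* differential feature within ±3 kb (one feature per gene, so a
gene flanked by a lost and a gained site is not double-counted) and
correlates feature logFC with expression log2FC; Spearman by default,
Pearson selectable.

Correlation ranking against a reference gene (the TCGA-style analysis)
computes Spearman rho and p per gene across samples and sorts by
sign(rho) × (−log10 p). For n <= 8 samples the p is an exact permutation
enumeration; beyond that the t-approximation is used.

## Pileups

Anchor pileups average the O/E submatrix centered on each anchor's diagonal
pixel and, by default, divide element-wise by the mean pileup over 10
equinumerous uniform anchor sets — one concrete reading of "relative to
randomised average genome-wide interaction"; with 0 random sets the raw O/E
average is returned, in which case a single anchor reproduces its window
exactly. Quadrant means summarise insulation: the two cross-anchor corner
quadrants against the two on-diagonal quadrants. Paired pileups average
windows centered on off-diagonal anchor-pair pixels with separation in
[100 kb, 2 Mb] (the window must not cross the diagonal). Aggregation is by
mean; anchors whose window leaves the matrix are dropped and counted.

## Synthetic genomes

The generator produces the study conditions the pipeline is validated on.

*Geometry.* Per chromosome, TAD sizes are uniform in [100 kb, 1 Mb] laid end
to end; each TAD receives 1–3 interior subTAD cuts respecting a 50-kb
minimum piece. Insulation factors (fraction of cross-boundary contacts
retained) are uniform in (0.08, 0.25) for TAD boundaries and (0.40, 0.65)
for subTAD boundaries — subTAD boundaries are systematically weaker,
consistent with subTADs being the dynamic, tissue-variable level.

*Contacts.* The Poisson mean for bins i < j is
`depth · (1+j−i)^−alpha · e(i,j) · f(i,j)` with alpha = 1, e multiplying
1.7 when the bins share a TAD and 2.5 when they share a subTAD, and f the
product of the insulation factors of intervening boundaries. depth = 100
gives bin row sums of order 1–2 × 10^3, the coverage scale of a ~600 M-read
Hi-C library at 10-kb bins. Optional per-bin lognormal factors add
coverage overdispersion (off by default); optional focal "loops" multiply
3×3 pixel neighbourhoods.

*Perturbation.* Genome-wide, 17% of subTAD boundaries are removed and 11%
added; 10% / 7% at the TAD level — the reorganisation scale of the
motivating system. Added boundaries fall within 100 kb of a removed one
with probability 0.7 (else uniform), reproducing the gained-next-to-lost
adjacency. The two perturbed clones share the perturbed hierarchy (clonal
architecture) with independent Poisson noise.

*Features.* A CTCF peak anchors every control boundary, plus ~10 background
peaks per Mb. A removed boundary's peak is truth-lost with probability 0.9
(the coupling parameter); a 2% baseline loss rate and 1.5% gain rate apply
everywhere. Truth-lost peaks start from half the constant occupancy in the
control — the weaker-occupancy signature of loss-prone sites — and drop a
further 2 log2 units in the perturbed condition. Replicate densities carry
lognormal noise (0.35 log2 units). Histone-mark sites appear at gained
subTAD boundaries with probability 0.9 (truth-gained, +2 log2), at 300
gene promoters with log-fold-changes latently correlated (rho = 0.6) with
the genes' expression changes, and as background. Expression tables place
40 genes per Mb; genes with a TSS within ±10 kb of a gained subTAD boundary
receive a +1 true log2FC. Observed tables come from 2 vs 2 negative-binomial
replicate counts (dispersion 0.05) passed through the package's own
differential test, so padj thresholds act on realistic p-values.

All placements flow from one seed through a single `numpy` Generator per
operation in documented draw order.

*What the generator does not emulate:* restriction-fragment effects, A/B
compartments, mappability structure, read-level noise, trans contacts,
motif-level CTCF biology. Passing tests therefore certify the statistical
machinery (calibration, recovery, invariances) on an idealised signal
structure, not performance on real sequencing artefacts.

## Validation problem sizes

The standard validation genome is 2 chromosomes × 20 Mb at 10-kb bins
(2,000 bins each); boundary recovery and the end-to-end pipeline run there
in seconds. Multi-seed sweeps (p-value calibration over 200 seeds,
qualitative insulation-loss patterns over 20 seeds) use a single 8-Mb
chromosome; oracle-equivalence checks use <= 100-bin matrices and <= 20
features, small enough for exhaustive or brute-force reference
computations.

## Known limitations

- Boundary strength, not window scale, separates the two levels; on data
  where TAD and subTAD boundary strengths overlap heavily the two-scale
  caller will mix levels, and the prominence thresholds must be re-tuned.
- The pooled-variance z-test assumes homoscedastic log densities; strongly
  occupancy-dependent noise would miscalibrate it.
- The balancing routine is dense (O(n²) memory per chromosome), adequate to
  a few thousand bins per chromosome but not genome-scale 1-kb maps.
- Exact Spearman p-values are enumerated only to n = 8 samples; above that
  the t-approximation is used.
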