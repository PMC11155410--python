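# Methods

This note documents the models behind `lineagemap`, the parameters that
matter, what the synthetic cohorts do and do not emulate, and the numerical
conventions that make every run reproducible.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not a biophysical simulation of breast tissue.

**Normal epithelium.** Seven subsets across three lineages (BM: basal,
myoepithelial; LP: LTF_LP, KRT23_LP; ML: AREG_ML, TNFSF10_ML, MUCL1_ML).
Counts are negative binomial (gamma–Poisson), parameterized by a per-gene
mean and a common dispersion θ (`nb_dispersion`, default 2.0; variance
m + m²/θ). Baseline per-gene means are log-normal(0, 1) across genes.
Each subset multiplies a disjoint 25-gene marker block by
`marker_fold_change` (default 6), and each lineage additionally shares a
25-gene block across its subsets — this shared block is what makes
lineages, not just subsets, recoverable. Library sizes are log-normal
(sd 0.3 on the log scale). Ten `MT-` genes on `chrM` carry a per-cell
mitochondrial fraction drawn Beta(2, 38) (mean 5%), with 3% of cells
drawn from Beta(8, 12) so the 15% QC threshold has work to do. Defaults:
2,000 genes, 150 cells per subset.

**Tumor cells.** Each of 600 cells draws a lineage from
`tumor_origin_fractions` (default 0.3/0.4/0.3) and expresses the mean of
that lineage's subset programs. Half the cells (`cnv_clone_fraction`) form
an aneuploid clone whose expression rates are multiplied by planted
segment copy ratios before count sampling. The default segments span
roughly 18% of the genome at arm-to-chromosome scale (gains of 1.5–3x,
losses to 0.5x), the burden scale typical of chromosomally unstable breast
tumors; the per-cell copy-ratio vector is stored as ground truth.

**Bulk mixtures.** Each of 100 samples is Σ_l p_l · m_l + N(0, σ²)
truncated at zero, where m_l is the lineage's mean library-normalized
(linear CP10K) expression over the normal cohort and p is drawn from a
flat Dirichlet. σ (`bulk_noise_sd`) defaults to 0.5, about 10% of the mean
per-gene signal at default sizes. Mixing is done in linear expression
space, matching the space in which the deconvolution basis is built.

**Rankings.** Multi-omics ranking fixtures give planted genes a large
evidence score plus seeded jitter; all lists share one gene universe.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects beyond cohort offsets, dropout beyond NB sampling, subclonal CNV
hierarchies, and any dependence of CNV burden on lineage. Tests passing on
these cohorts show the algorithms recover the structure they assume; they
do not certify performance on real tissue.

## Preprocessing

QC boundaries are strict by convention: cells with detected genes < 200 are
removed (exactly 200 kept); cells with mitochondrial fraction > 0.15 are
removed (exactly 0.15 kept); genes nonzero in < 3 cells are removed
(exactly 3 kept). Cells are filtered before genes. Judgment-based removal
of contaminating clusters/doublets in real data is replaced by an explicit
cell blocklist argument. Normalization is counts-per-10⁴ + log1p;
clustering is PCA (15 components on standardized genes) → kNN graph →
Leiden, seeded; the resolution is a knob (default 1.0) because no single
value suits every cohort size. Pseudobulk profiles are per-cluster means of
normalized expression with provenance (origin kind, label, cell count).

## Projection and group assignment

"Redundancy elimination" of subset markers is implemented as plain
deduplication of the union of per-subset top-100 one-vs-rest rank-sum
markers (positive direction only). The top-1% variable-gene rule uses
⌈0.01 · n_genes⌉ with ties broken by gene id; at transcriptome scale this
is the published 1%, but scaled-down cohorts need a larger fraction to
yield a workable meta-gene space (the test fixtures use 10% at 800 genes).
Batch correction across the tumor and normal pseudobulk cohorts is
per-cohort gene standardization — exact for additive cohort offsets, and
well-posed on pseudobulk profiles where cell-level anchor methods are not.
The 122-profile-style clustering is hierarchical with correlation distance
and average linkage, cut at k = 3; each group takes the lineage of the
normal references it contains, and a group with zero or mixed-lineage
references is an error rather than a guess.

## D-distance markers and DWLS

The correlation plane assigns x = Spearman ρ with BM composition and
y = Spearman ρ with LP composition. Under this assignment the flags (0,1),
(1,1), (1,0) read as LP-specific, LP/BM-shared and BM-specific, which is
the only orientation in which the published union rules produce
discriminative LP and BM sets; "top 150 of D" means the 150 smallest
distances. Lineage compositions come from the projected per-sample lineage
cell fractions. Markers shared between LP and BM (through D2) enter the
basis once.

The solver: p̂⁰ from nonnegative least squares; then iterate weighted NNLS
with per-gene weights w_g = 1/max((S·p̂)_g², 10⁻¹²), dampened by capping
w at d · min(w). The constant d is selected per sample from {1, 2, 4, 8,
16, 32} by 4-fold cross-validation over genes (fit on 3 folds with capped
weights, score squared reconstruction error on the held-out fold; a
20-iteration budget inside CV is enough to rank constants). Iteration
stops at ‖Δp‖∞ < 10⁻⁶ or 100 iterations; the final p is clipped at zero
and renormalized. On noiseless synthetic mixtures the solver agrees with
plain NNLS to machine precision, as it should — dampening only matters
when heteroskedastic noise makes highly expressed genes dominate.

## Signature scoring

Single-sample enrichment is a weighted KS running sum on expression ranks:
genes sorted by decreasing expression (ties broken by gene id), set members
contribute rank^0.25 increments normalized to sum 1, non-members a flat
1/(N − |set|) penalty, and the score is the running sum's signed value at
its largest absolute deviation, so scores lie in [−1, 1] and are invariant
to monotone transforms of a sample's expression. This is a documented
substitute for kernel-based GSVA, which the original analysis used as a
black box; equivalence to GSVA is not claimed — only the downstream
difference-of-scores construction and its recovery properties.

The LP score is ES(positive) − ES(negative) with marker sets from the
top/bottom-100 correlations with LP proportion; "higher than the median"
is strict, so median ties fall in LP-low. On synthetic cohorts the
positive-set score alone tracks the true LP fraction almost perfectly
(ρ ≈ 0.99), while the negative-set score also responds to the BM:ML
balance, which a flat Dirichlet varies independently of LP; the combined
score's Spearman correlation with the true LP fraction therefore ranges
about 0.87–0.99 across generator seeds (0.96 at the default seed). The
construction is kept as published rather than tuned.

Module scores (per-cell signatures) subtract the mean of seeded control
genes drawn from the same average-expression bins (25 bins, 100 controls
per set gene); controls exclude the set genes themselves, otherwise a
strongly induced set contaminates its own background.

## CNV profiles and the instability screen

The profile of a cell is its log-normalized expression minus the mean of
the reference cells, smoothed per chromosome by a centered moving average
(window 101 genes, truncated at chromosome ends — a window wider than the
chromosome degrades to the chromosome average), clipped to ±3 and
re-centered by the cell's median. Each gene's smoothed value is one
"region". This is deliberately the subtraction-and-smoothing core of
expression-based CNV inference, without HMM state calling or denoising:
only the variance feeds downstream logic. The CNV score uses the
population variance (divisor n), fixed for determinism. The reference cell
set is a required argument — results depend on it, and no default could be
defended.

The quartile screen compares the top ⌈q·n⌉ against the bottom ⌈q·n⌉
cells by CNV score (q = 0.25) within the LP group, per gene, with a
normal-approximation rank-sum test (tie-corrected) and Benjamini–Hochberg
adjustment at α = 0.05.

## Rank aggregation

Within the intersection of K ranked lists of common size N, each list is
re-oriented so its strongest gene carries rank value N and its weakest 1;
a gene's rank score is the sum over lists, bounded by [K, K·N]. Re-ranking
inside the intersection (rather than summing full-list positions) makes
the bounds independent of the source lists' lengths; whether the original
analysis did this is unstated, so the choice is documented here. Ties
break first by a list's own order, finally lexicographically.

## Problem sizes and determinism

Default cohort sizes (2,000 genes; 1,050 normal and 600 tumor cells; 100
bulk samples) were chosen so that every recovery property is measurable
with comfortable margins while a full pipeline run stays under a minute;
the unit-test fixtures are smaller still (800 genes, 60 cells per subset).
All randomness flows through `numpy.random.default_rng` generators seeded
from a single integer per cohort or stage, so identical configurations
reproduce bit-identical counts, labels and manifests; the pipeline
manifest records parameters, seeds and SHA-256 checksums of every output.

## Known limitations

- The generator's lineage programs are linear mixtures of subset means;
  real tumors drift away from their origin program, which would blur the
  projection step more than these tests show.
- Deconvolution accuracy is reported under Gaussian bulk noise; real bulk
  cohorts add platform effects the basis does not model.
- The GSVA substitute shares ranks-only invariances with GSVA but not its
  kernel CDF; LP scores are comparable within a cohort, not across tools.
- CNV inference has gene-level resolution and no state calling; focal
  events smaller than the smoothing window are attenuated.
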