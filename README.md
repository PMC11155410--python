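# lineagemap

Breast cancers arising from the same organ can descend from different normal
epithelial cells. The mammary epithelium contains three lineages — basal /
myoepithelial cells (**BM**), luminal progenitors (**LP**) and mature luminal
cells (**ML**) — and which of them a tumor's founding cell resembled shapes
the tumor's biology, including its degree of chromosomal instability.
`lineagemap` is a Python toolkit for mapping that *cell of origin* from
transcriptomes and for following the consequences through to candidate drug
targets. It is aimed at computational biologists working with single-cell
and bulk breast-tumor expression data.

The package implements five connected analyses:

1. **Single-cell preprocessing** — QC (cells with < 200 detected genes or
   > 15% mitochondrial counts removed; genes seen in < 3 cells removed),
   log CP10K normalization, PCA + Leiden clustering, and pseudobulk
   aggregation of clusters into mean-expression profiles.
2. **Tumor–normal projection** — tumor pseudobulk profiles and
   normal-epithelium reference profiles are restricted to a *meta-gene*
   space (the intersection of per-subset top-100 markers with the top-1%
   most variable tumor genes), batch-corrected by per-cohort gene
   standardization, and clustered (correlation distance, average linkage)
   into three groups labelled BM / LP / ML by the references they contain.
3. **Bulk deconvolution** — every gene is placed at coordinates
   (x, y) = (Spearman ρ with BM composition, Spearman ρ with LP composition),
   and squared distances to three flags select lineage markers:

       D1 = x² + (y−1)²       (LP-specific flag at (0,1))
       D2 = (x−1)² + (y−1)²   (LP/BM-shared flag at (1,1))
       D3 = (x−1)² + y²       (BM-specific flag at (1,0))

   LP markers = union of top-150 smallest D1 and D2; BM markers = union of
   top-150 smallest D2 and D3; ML markers = top-150 by ρ with ML
   composition. A dampened weighted least-squares (DWLS) solver — iteratively
   reweighted nonnegative least squares with weights 1/(S·p)² capped at a
   cross-validated multiple of the minimum weight — estimates per-sample
   (BM, LP, ML) proportions from bulk expression against the marker basis.
4. **LP signature score** — top/bottom-100 genes by correlation with the LP
   proportion define positive/negative marker sets; a sample's LP score is
   the difference of their single-sample rank-enrichment (weighted
   Kolmogorov–Smirnov) scores, and the cohort median splits LP-high from
   LP-low tumors.
5. **CNV instability and target ranking** — per-cell copy-number profiles
   are inferred by reference subtraction and chromosome-wise smoothing of
   expression; the **CNV score** is the variance of a cell's profile.
   Genes differentially expressed between the top and bottom CNV-score
   quartiles join ranked evidence from other omics layers, and each gene's
   **rank score** (the sum of its within-intersection ranks across layers,
   best = N) orders the candidate chromosomal-instability drivers.

A synthetic-data generator (`lineagemap.synthetic`) supplies every input
with known ground truth — a 7-subset normal epithelium, tumor cells with
planted aneuploidy, bulk mixtures with known proportions, and concordant
multi-omics rankings — so the whole pipeline is testable end to end.

## Worked example

```python
import lineagemap as lm

result = lm.run_all(lm.PipelineConfig())   # generator defaults, seed 0
print(result.meta_genes.n_intersection)    # 20 meta-genes
print(result.origin.profile_group.value_counts().to_dict())
#  {'ML': 5, 'BM': 4, 'LP': 4}  -> 3 groups over 13 tumor + 7 normal profiles
```

On the default synthetic cohort this run prints, among other things:

```
cell origin accuracy: 1.0      # projected vs generative lineage, 570 cells
deconv MAE:           0.003    # |estimated - true| mixing proportions
LP score Spearman:    0.962    # LP score vs true LP fraction, 100 bulks
CNV AUC:              0.988    # CNV score separating planted CNV clones
bulk subtypes:        {'Mixed': 29, 'ML': 25, 'BM': 25, 'LP': 21}
```

meaning: every tumor cell was assigned its generative lineage, bulk mixing
proportions were recovered to within 0.3 percentage points on average, the
LP score tracks the true LP content, and the per-cell variance score cleanly
separates the planted aneuploid clone from copy-neutral tumor cells. The
same stages are available from the shell:

```sh
lineagemap simulate --outdir data/
lineagemap run-all --outdir run/ --seed 0    # writes manifest.json
```

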