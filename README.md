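# cnloss

Transcriptional gene-loss signatures from tumor copy-number and mutation
data.

`cnloss` asks a simple question of a tumor cohort: *what does the
transcriptome look like when a particular gene is lost?*  Instead of
engineering a knockout cell line, it treats the cancer genome as the
perturbation experiment.  Given a target gene α and a cohort with matched
copy-number (CNV), somatic-mutation and RNA-seq count data, it:

1. **Partitions the cohort** into an *inactivated* set — samples where α is
   deleted (a GISTIC-like copy-number score < −1 on a segment overlapping
   the α locus) or carries a user-listed inactivating mutation (missense
   substitutions, or stop-gains up to a `STOP N` position bound) — and a
   structurally quiet *control* set: copy-neutral at α, free of non-neutral
   CNVs larger than 1 Mb anywhere, and free of any α mutation.  The
   analysis proceeds only when there are ≥ 5 inactivated samples and the
   inactivated/control ratio exceeds 0.05.
2. **Extracts the loss signature** two ways on CPM-filtered counts
   (CPM > 5 in ≥ 5 samples):
   - *Differential expression*: per-observation precision weights from the
     mean–variance trend of log₂-CPM (the voom procedure), gene-wise
     weighted least squares y_g = β₀ + β·group + ε, empirical-Bayes
     shrinkage of residual variances s²_g toward a scaled-F prior
     (s²_post = (d₀s₀² + d s²_g)/(d₀ + d)), moderated t-statistics on
     d₀ + d df, and Benjamini–Hochberg q-values, with per-group median CPM
     columns.
   - *Random forest*: a 500-tree Gini-split classifier (inactivated vs
     control) over the same genes, ranked by mean decrease in Gini (MDG,
     as a percentage of the forest total) with out-of-bag mean decrease in
     accuracy (MDA) alongside, plus a report of how many top-100 MDG genes
     are DE-significant.

It is written for computational biologists mining TCGA-style cohorts for
gene-loss biomarkers or "parent" signatures of a deletion, and ships with a
seeded synthetic-cohort generator so the whole workflow is testable with no
external data.

## Worked example

Generate a synthetic 120-sample cohort with a planted −1.5 log₂ loss of the
target gene (12 focal deletions, 3 inactivating mutations, a 20-gene
downstream signature), then run the workflow:

```bash
cnloss simulate --seed 42 --out demo/cohort
cnloss run --gene TARGET \
    --counts demo/cohort/counts.tsv \
    --seg demo/cohort/segments.seg.tsv \
    --mutations demo/cohort/mutations.tsv \
    --loci demo/cohort/loci.tsv \
    --inactivation-list demo/cohort/inactivating.txt \
    --seed 7 --out demo/out
```

The run manifest (`demo/out/manifest.json`) summarises the fit:

```
"n_inactivated": 15, "n_control": 103, "ratio": 0.1456,
"gates_passed": true, "genes_tested": 2000,
"d0": 1251.7, "s0_squared": 1.005,
"n_significant_q05": 23, "oob_accuracy": 0.941,
"top100_rf_significant_in_de": 22
```

All 15 planted loss samples were recovered (12 by deletion, 3 by mutation);
the two samples with an unlisted α mutation were excluded from the control
set.  The large prior df (d₀ ≈ 1252) says the gene-wise variances are
nearly homogeneous after precision weighting, so shrinkage is strong.  In
`demo/out/de.tsv` the target gene reads

```
gene    logFC     AveExpr  t        p           q           median_cpm_inactivated  median_cpm_control
TARGET  -1.57693  6.18804  -11.9265 2.87902e-31 7.19756e-29 25.9363                 87.6757
```

— the planted −1.5 log₂ downregulation is recovered (estimated −1.58,
q ≈ 7·10⁻²⁹; median CPM 26 in inactivated vs 88 in control samples).
`demo/out/rf.tsv` ranks genes by Gini share; the target sits at rank 4 with
3.1% of the forest's impurity decrease, behind planted signature genes:

```
gene    mdg_percent  mda         rank
G0007   4.26823      0.00683281  1
G0005   3.87783      0.00807084  2
```

The same analysis is available as library objects:

```python
from cnloss import GeneLossSignatureModel, PipelineConfig
model = GeneLossSignatureModel.from_files(
    "counts.tsv", "segments.seg.tsv", "mutations.tsv", "loci.tsv",
    PipelineConfig(target_gene="TARGET", seed=7),
    inactivation_list_path="inactivating.txt")
results = model.fit()
print(results.summary())      # gate report, d0, s0^2, target-gene DE line
results.de_, results.rf_      # the two signature tables (DataFrames)
```

Exit codes of `cnloss run`: 0 success, 3 sample-size gates failed
(partition and manifest still written), 1 error.

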