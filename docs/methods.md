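# Methods

## The model

`cnloss` estimates the transcriptional consequence of losing one gene α in
a tumor cohort by contrasting two observational groups that stand in for
the arms of a knockout experiment.

**Partition.** Only samples profiled on both the CNV and the mRNA platform
are candidates (samples on one platform are recorded as excluded with a
missing-data reason).  A candidate is *inactivated* when

- a copy-number segment overlapping the α locus (≥ 1 bp, 1-based inclusive
  coordinates, strand-agnostic) has a GISTIC-like score strictly below the
  deletion threshold (default −1, so −2 "deep deletion" calls qualify and a
  boundary −1 does not), optionally restricted to deletions strictly longer
  than `min_deletion_size` (default 0 = off); or
- it carries an α mutation matching the user's inactivating list: an exact
  (ref, position, alt) missense match, or a stop-gain at position ≤ N from
  a `STOP N` line.  Unparseable protein changes (frameshifts, `p.?`,
  splice notation) never match — the filter fails closed.

Under the `mutations_only` strategy the deletion route is disabled.

A candidate not inactivated joins the *control* set unless (in priority
order, one recorded reason per sample): a non-neutral (score ≠ 0) segment
overlaps α; a non-neutral segment anywhere exceeds `control_max_cnv_size`
(default 1 Mb); or any α mutation record exists for the sample, regardless
of predicted effect.  The first rule uses any non-neutral call, not only
deletions, because the control must be copy-neutral at α; the third is
deliberately conservative about control purity.  Copy-neutral segments of
any size never exclude.

Downstream analysis runs only when n_inactivated ≥ 5, the control set is
non-empty, and n_inactivated / n_control > 0.05 (both inequalities strict
at the boundary).  A gate failure is a reported outcome with enumerated
reasons (exit code 3 from the CLI), not an error — batch screens over many
gene–cohort pairs need to tally why analyses fail.

**Expression filtering.** Counts are converted to CPM
(count / library size × 10⁶, offset-free) and genes kept when CPM > 5 in
≥ 5 samples (both strict/at-least as written).  Library sizes are the
column sums of the *unfiltered* matrix and are frozen: filtering must not
silently rescale the data.  The filter is idempotent and monotone in both
thresholds.

**Differential expression.**  The modelling transform is
y = log₂((count + 0.5)/(libsize + 1) × 10⁶).  The pipeline reimplements
the published precision-weighting and moderation formulas:

1. *Mean–variance trend.*  Per-gene OLS of y on the (intercept, group)
   design gives residual sd s_g and mean log-CPM ȳ_g.  √s_g is smoothed
   against average log₂ count (ȳ_g + mean_j log₂(L_j + 1) − log₂10⁶) by
   LOWESS with span 0.5, 3 robustness iterations and interpolation delta
   0.01 × range — the defaults of the reference R `lowess` that the
   canonical implementation calls.  Each observation's fitted log-count is
   looked up on the trend (linear interpolation, constant extrapolation)
   and its weight is trend⁻⁴.  If no gene has residual variation the trend
   is undefined and unit weights are used with a warning; fewer than 10
   genes is an error advising to relax the filters.
2. *Weighted fit.*  Gene-wise WLS (batched with einsum over a shared
   design) yields β (log₂FC, negative = lower in inactivated), unscaled sd
   u = √[(XᵀWX)⁻¹]₂₂, and s² on d = n − 2 df.
3. *Moderation.*  Under the hierarchical model s² ~ s₀²·F(d, d₀).  With
   e_g = log s²_g − ψ(d/2) + log(d/2), d₀ solves
   ψ′(d₀/2) = var(e) − ψ′(d/2) via the inverse trigamma (Newton), and
   s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).  When the observed
   log-variances underdisperse pure sampling noise, d₀ = ∞ and s₀² is set
   to the geometric mean of the positive s² so that homogeneous variances
   pass through unchanged and the moderated t reduces exactly to the
   classical pooled t — the natural zero-dispersion limit of the model.
   Zero variances (exact fits) are excluded from the moment estimation but
   are shrunk by the resulting prior.  Posterior variances are
   s²_post = (d₀s₀² + d s²)/(d₀ + d); moderated t = β/(u·s_post) on
   d₀ + d df, capped at the pooled df Σ_g d so an infinite prior yields a
   finite reference distribution.
4. *Multiplicity.*  q-values are Benjamini–Hochberg adjusted p-values
   (delegated to `statsmodels.multipletests`).  The output table adds
   per-group median plain-CPM columns and sorts by q, ties by |log₂FC|.

The whole DE path is deterministic given its inputs and is cross-validated
in the test suite against Bioconductor limma (voom → lmFit → eBayes, run
through Rscript) on a seeded 200 × 16 dataset: log-fold-changes, moderated
t, d₀ and s₀² all agree to ≈ 1e−10/1e−4, far inside the 1e−6 (logFC) and
1e−3 (t) test tolerances that allow for smoothing-implementation
differences.

**Random forest.**  The classifier is a seeded bagging of CART trees
(scikit-learn `DecisionTreeClassifier`: Gini splitting, √G candidate
features per split, no depth limit), with the bagging layer written here
so per-tree bootstrap membership is explicit.  That bookkeeping provides
out-of-bag accuracy, per-tree unnormalised impurity decreases, and the
classical OOB permutation importance: for each tree and gene, the gene's
values are permuted among that tree's OOB samples and the accuracy drop is
averaged over trees (MDA).  MDG is the per-gene mean impurity decrease
normalised to sum to 100% over genes — raw impurity sums depend on
implementation scale, percentages do not.  Because inactivated sets are
typically far smaller than control sets, trees use balanced class weights
by default (switchable).  Ranks break ties lexicographically by gene id;
all outputs are deterministic under a fixed seed.  The DE–RF comparison
counts how many of the top-k (default 100) MDG genes fall below the DE
significance threshold and emits the paired rank-vs-q series for plotting.

## Synthetic cohorts

The generator emulates the data regime the pipeline is built for: a
TCGA-like cohort with matched SEG segments, a protein-change mutation
table, raw NB counts and a locus table, all reproducible byte-for-byte
from one integer seed through a single numpy Generator.

Defaults (chosen once as a realistic mid-sized cohort): 120 samples, 2000
expressed genes; a TP53-like target locus (chr17:7,565,097–7,590,856); 12
samples with a planted focal deep deletion (score −2, 60 kb) over the
target and 3 with a listed inactivating mutation; one background CNV per
sample on average (score ±1, log-uniform 10–500 kb, never overlapping the
target in intended-control samples) plus a genome-style copy-neutral
segment for every sample; 2 samples with an unlisted α missense (excluded
from control only); baseline log₂ abundances N(5, 1.5) normalised to
per-sample proportions; library sizes log-normal around 10⁷ (sd 0.2 on the
log scale, mean-corrected); NB dispersion 0.1; target effect −1.5 log₂ and
a 20-gene downstream signature at ±1.5 log₂ in inactivated samples.  The
deletion's expression effect is planted directly as a mean shift — the
pipeline only observes counts, so a mechanistic dosage model would be
indistinguishable downstream.

What the generator does *not* model — recurrent breakpoints, tumor purity
and subclonality, VAF, demographic structure, batch effects, correlated
co-expression modules — bounds what green tests mean: they demonstrate the
algorithmic contract (rule fidelity, calibration, recovery of planted
effects under NB noise), not robustness to the full messiness of real
tumor data.

## Numerical and design choices

- Coordinates are 1-based inclusive internally; BED input is converted at
  the boundary (involution tested).  Overlap requires ≥ 1 shared bp.
- Sample matching is exact string equality, optionally after barcode
  truncation (e.g. 15 characters) for TCGA-style aliquot suffixes.
- The optional deletion-size filter keeps deletions strictly *larger* than
  the threshold, as configured; it defaults to off.
- Weight trend values are floored at 1e−10 before the ⁻⁴ power; residual
  sds below 1e−10 count as exact fits.
- `estimate_prior` requires ≥ 2 genes and errors when every variance is
  zero (no residual variation to model).
- Forest trees receive independent seeds drawn from the master Generator;
  MDA uses a fresh permutation per (tree, gene).
- Problem sizes in the test and acceptance runs (hundreds to 2000 genes,
  tens of samples, 100–500 trees, 20 effect-recovery replicates) are the
  package's chosen desk-scale study conditions; they keep every check
  cheap while leaving all statistical margins wide.

## Known limitations

Two-group design only (no covariates, no purity or demographic
adjustment); no TMM/quantile normalisation (not part of the modelled
workflow); no VAF-aware mutation filtering (TCGA MAFs largely lack VAF);
no amplification mode; thresholded GISTIC calls are taken at face value.
Cohort-scale screens across many gene–dataset pairs are supported by the
exit-code contract but the screening driver itself is out of scope.
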