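# Methods

`gctme` implements a digital-cytometry pipeline for the gastric-cancer
tumor microenvironment (TME): from an annotated single-cell reference it
derives cell populations and a signature matrix, estimates cell-population
fractions in bulk transcriptomes by support-vector regression, summarizes
each sample by ratio scores — chiefly the STEM score — and relates scores
and TME subtypes to overall survival. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Single-cell preprocessing

Input is a genes × cells count matrix with per-cell labels: cell type,
subject (biopsy), and disease stage along the gastritis-to-early-cancer
cascade (NAG → CAG → IM → EGC). QC applies three filters in a fixed order:

1. **Type level** — keep cell types with more than `min_cells_per_type`
   (default 20) cells that appear at `min_stages_per_type` (default 2) or
   more stages. Types confined to one stage cannot inform the
   stage-resolved cluster tree.
2. **Cell level** — drop cells expressing fewer than `min_genes_per_cell`
   (default 500) genes; a cell at exactly the threshold is kept (the rule
   is a strict "fewer than").
3. **Gene level** — drop genes detected in fewer than
   `min_gene_cell_fraction` (default 2%) of the remaining cells.

The order matters: gene detection fractions are computed after cell
removal, so swapping steps 2 and 3 changes the result slightly. QC is
idempotent.

Pseudobulk columns are element-wise count sums over all cells sharing a
grouping key — (cell type, subject) for population discovery, (population,
subject) for signature construction. TPM normalization scales each column
to 10⁶. No gene-length term is used: the reference is 3'-tag droplet data,
where counts are already per-transcript; a gene-length vector can be
supplied for full-length protocols, turning the same function into
classical TPM.

## Population discovery

Genes are ranked by how specifically they track cell type rather than
donor. For each gene, a two-way additive ANOVA (main effects cell type and
subject, no interaction) is fitted to log2(TPM + 1) pseudobulk values, with
type-II sums of squares so unbalanced designs are handled; the ranking
criterion is the ratio F_celltype / F_subject, with F_subject = 0 genes
placed above all finite ratios ordered by F_celltype. Zero-variance genes
are excluded and counted. The additive model, the log2 transform and the
pseudocount of 1 are our choices where the procedure is otherwise
underdetermined; the ratio is the simplest monotone formalization of
"high cell-type F relative to subject F". The implementation solves all
genes at once through shared projection (annihilator) matrices; tests
verify it against a from-scratch sums-of-squares computation on balanced
designs to 1e-8.

The top N genes (default 100) restrict the (cell type, stage) mean-TPM
profiles; the cluster tree uses Ward linkage on the distance 1 − r², where
r is the Pearson correlation of log2-transformed profiles. Note that this
metric treats perfect anti-correlation as zero distance; it is implemented
as stated, with 1 − r available as a config alternative. Cutting the tree
at k = 10 yields the cell populations; each cell inherits the population of
its (cell type, stage) leaf. The analysis driver names clusters by their
dominant member type (cancer-led → EMEC, enterocyte-led → PMEC,
fibroblast/smooth-muscle → Stromal, …). Stability of the cut across
N ∈ {50, 100, 150, 200} is reported as an adjusted-Rand diagnostic.

## Signature matrix

Markers for a population are genes with (mean TPM + 1) / (other-populations
mean TPM + 1) ≥ 2 and one-way ANOVA p ≤ 0.01 for that population's
(population, subject) pseudobulk profiles against all others — pseudobulk,
not single cells, is the replication unit, avoiding pseudo-replication.
Survivors are ordered by descending fold change (ties: smaller p, then gene
id, making the gene count reproducible) and the top M per population are
kept. The signature matrix holds per-population mean TPM over the union of
markers; genes marking several populations appear once.

M is chosen by self-validation: an artificial bulk is formed by summing
counts over each biopsy's cells, whose true fractions are the biopsy's
per-population cell-count shares (UMI-mass shares behind a flag); for each
M on a grid the rebuilt signature deconvolves this artificial bulk and the
mean per-biopsy RMSE against truth is recorded (Pearson r alongside).
Smallest M wins ties. The analysis driver uses a grid of 25–125 matched to
the synthetic reference's 60 planted markers per type; the package default
grid is 50–250 in steps of 50.

Immune fractions come from a fine-type immune signature deconvolved the
same way and then merged into 7 lineages (adaptive T, innate T, adaptive B,
NK, monocytes, dendritic, granulocytes) by exact fraction summation. The
package does not bundle a published sorted-immune signature; it accepts any
fine-type signature plus a lineage map, and ships a synthetic immune
signature (labelled as such) for tests and demonstrations.

## Deconvolution

Fractions are estimated per sample by linear ν-SVR of the mixture on the
signature columns, following the published CIBERSORT recipe: z-score the
mixture per sample and the signature globally; fit at ν ∈ {0.25, 0.5,
0.75}; keep the ν with the lowest reconstruction RMSE on signature genes;
clip negative coefficients to zero and renormalize to sum 1. Output rows
are therefore relative fractions on the probability simplex, per
compartment (non-immune or immune) — never absolute abundances; comparing
a fraction across samples is meaningful, comparing non-immune with immune
magnitudes is not. Standardization makes estimates invariant to positive
rescaling of a mixture. The libsvm tolerance default is 1e-5: noiseless
recovery is then accurate to ~1e-6 while remaining fast (tighter tolerances
can stall libsvm without accuracy gains). Goodness of fit (RMSE, Pearson r)
is reported per sample with both reconstruction and mixture standardized,
since renormalized fractions lose the coefficient scale of the fit.
Cross-platform batch correction is reduced to optional per-gene quantile
matching of the bulk to the signature's pooled distribution (off by
default); full batch-correction modes are out of scope.

## Scores

Populations are "non-rare" when their cohort-mean fraction exceeds 5% of
the compartment; ratio scores f_A / (f_B + ε) are emitted for every ordered
pair of non-rare populations. The STEM score is

    STEM = f_EMEC / f_Stromal + f_Tadaptive / f_Monocytes

combining the most prognostic non-immune factor (early-malignant epithelium
over stroma) and immune factor (adaptive T cells over monocytes); higher
STEM is protective. ε (default 1e-6) guards denominators because clipping
can output exact zeros. In the cohort analysis drivers ε = 0.01 is used
instead: a deconvolved fraction below 1% is at the method's detection
limit, and the 1e-6 guard would otherwise turn an estimated-zero monocyte
fraction into a score of order 10⁶, dominating every downstream statistic.
When all denominators are comfortably positive the two choices agree.

## Stratification

**Optimal cutoff.** The score is dichotomized at each empirical quantile on
a grid (0.10–0.90, step 0.01); each split is tested by univariate Cox
(Wald p; log-rank by config) and the minimal-p cutoff is returned, ties to
the smaller quantile, with grid points yielding a zero-event group skipped.
The grid-minimal p is optimistically biased by multiplicity and is reported
as a selection criterion, not an honest test — a property the test suite
documents by showing null data rarely reach p < 0.001.

**TME subtypes.** Spectral clustering on the four STEM population fractions
(EMEC, Stromal, Tadaptive, Monocytes) with an RBF affinity; the bandwidth
defaults to the median pairwise distance. The cluster count is either fixed
(k = 3 is the reproduction default, the published subtype count) or chosen
by majority vote of four validity indices — silhouette,
Calinski–Harabasz, Davies–Bouldin, and the gap statistic — computed on
Ward/Euclidean partitions over k ∈ 2..6, falling back to 3 when no
majority forms. A 26-index panel would be out of proportion here; the
4-index panel recovers well-separated structure (planted blobs give k = 3
unanimously) but, like any such panel, can prefer a smaller k on heavily
overlapping clouds. Clusters are named by composition: H = highest mean
Stromal + Monocytes (the poor-prognosis, stroma-rich subtype), L = highest
mean EMEC + Tadaptive among the rest, M = remainder.

## Survival statistics

Kaplan–Meier curves and the log-rank test come from lifelines; Cox models
use Efron tie-handling and Wald confidence intervals, with `stage` expanded
against reference level I and non-convergence flagged rather than raised.
Benjamini–Hochberg controls the FDR over p-value families. Fixed-effects
meta-analysis pools per-cohort log hazard ratios by inverse-variance
weights: β̂ = Σwᵢβᵢ/Σwᵢ, se = (Σwᵢ)^(−1/2), wᵢ = 1/seᵢ², with a z-test for
the overall effect; with equal standard errors it reduces to the simple
mean, and the pooled se never exceeds the best single study's.

The marker-gene screen fits, per gene and cohort, a multivariate Cox model
of survival on standardized expression (hazard ratios are per SD; the scale
is configurable) plus whatever clinical covariates the cohort carries
(age, sex, stage, Lauren histology, treatment flags — cohorts with missing
covariates simply drop them). A gene passes a cohort at p < 0.05 with the
required direction — HR > 1 for stromal markers (stroma-rich is risk),
HR < 1 for EMEC markers (epithelium-rich is protective). Genes passing in
all cohorts (falling back to all-but-one when the strict rule selects
nothing, which is how the protective direction behaves on sparse signals)
are pooled by fixed-effects meta-analysis and selected at overall
p < 1e-5.

## Synthetic data: what it emulates, what it does not

The generators define the testbed. Single-cell counts are negative
binomial (variance μ + αμ², default α = 0.5) around log-normal baseline
means, with disjoint marker sets per cell type elevated `marker_fold`-fold
(default 8) and log-normal per-(subject, gene) effects (default sd 0.2)
giving the ANOVA a non-trivial subject factor; no gene-length structure is
simulated because the emulated reference is droplet data. Bulk mixtures
are exactly signature · proportions perturbed by multiplicative log-normal
noise (default sd 0.2 in the cohort analyses). Survival times are
exponential (Weibull by config) with log-hazard linear in the centered
score and independent exponential censoring; the cohort analyses plant
β = −0.105 per STEM unit (HR ≈ 0.90), the per-unit scale of a continuous
prognostic score.

The cohort drivers simulate four cohorts of 300/192/433/415 samples whose
mixing proportions come from three latent microenvironment groups
(stroma/monocyte-rich, intermediate, epithelium/T-rich), so subtype
structure exists but overlaps — as real cohorts do.

What passing tests show: the pipeline recovers planted compositions,
markers, cutoffs, cluster structure and hazard ratios under its own
generative assumptions, and its statistics match independent oracles
(non-negative least squares, textbook sums of squares, brute-force partial
likelihood, closed-form pooling). What they do not show: robustness to
cross-platform effects, to signature/bulk mismatch beyond log-normal
noise, to dropout structure beyond the negative binomial, or to violated
proportional hazards — none of which the generators emulate.

## Numerical choices and degenerate inputs

- Marker fold changes use pseudocount 1 in numerator and denominator;
  a gene expressed in exactly one population gets the largest finite fold
  change.
- Deconvolution requires ≥ `min_overlap_genes` shared genes (default 100)
  and rejects all-zero or constant mixtures by name; a fit whose clipped
  coefficients are all zero falls back to uniform fractions.
- Constant score vectors cannot be dichotomized and raise; quantile grid
  points with a zero-event group are skipped with a warning.
- Merge-height ties in the cluster tree follow scipy's merge order; exact
  RMSE ties in the M grid and p ties in the cutoff grid resolve to the
  smaller value.
- All generators, the subtype seed and the gap-statistic reference draws
  are deterministic under their seeds.

## Problem sizes

The shipped analyses run at desk scale, chosen to keep every stage
exercisable end-to-end: a 1,600-cell × 3,000-gene reference (11 cell
types, 9 subjects, 4 stages), 60 planted markers per type, four bulk
cohorts totalling 1,340 samples, and 100-replicate null studies for CI
coverage. Full-cohort accessions and their platform-specific normalization
are deliberately out of scope.
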