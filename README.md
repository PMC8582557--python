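# gctme — digital cytometry of the gastric-cancer tumor microenvironment

`gctme` estimates the cellular composition of gastric-cancer (GC) bulk
transcriptomes and turns it into prognosis. It is written for computational
oncologists who have (i) an annotated single-cell reference of the gastric
mucosa and (ii) bulk expression cohorts with overall-survival follow-up,
and who want a tested, end-to-end path from counts to patient
stratification.

The pipeline:

1. **Reference processing** — QC-filter annotated single-cell counts,
   summarize them into TPM pseudobulk per (cell type, subject).
2. **Population discovery** — rank genes by a two-way ANOVA criterion
   (F_celltype / F_subject on log₂ TPM) and cut a Ward tree on 1 − r²
   correlation distances over (cell type, stage) mean profiles into cell
   populations, including the early-malignant epithelial population (EMEC).
3. **Signature matrix** — select population markers (fold change ≥ 2,
   ANOVA p ≤ 0.01, top M by fold change), choose M by deconvolving an
   artificial per-biopsy bulk with known fractions.
4. **Deconvolution** — estimate relative population fractions of each bulk
   sample by linear ν-SVR against the signature (CIBERSORT-style: best ν by
   reconstruction RMSE, negative coefficients clipped, rows renormalized to
   the simplex).
5. **Scoring** — pairwise fraction ratios among non-rare populations and
   the STEM score,

   STEM = f_EMEC / f_Stromal + f_Tadaptive / f_Monocytes,

   combining the strongest non-immune and immune prognostic factors
   (higher STEM → lower hazard).
6. **Stratification & survival** — survival-optimal STEM cutoff over a
   quantile grid (univariate Cox per split), spectral TME subtypes (H/M/L)
   on the four STEM population fractions, Kaplan–Meier/log-rank,
   uni/multivariate Cox with BH-FDR, inverse-variance fixed-effects
   meta-analysis across cohorts, and a prognostic marker-gene screen.

A synthetic-data module generates single-cell counts with planted markers,
signature-weighted bulk mixtures with known proportions, and survival times
with a planted STEM effect, so the whole pipeline is testable without any
download. See `docs/methods.md` for models, parameters and limitations.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic
cohorts and write tables under `results/`:

```bash
python analysis/01_simulate_reference.py     # 1,600 cells x 3,000 genes
python analysis/02_discover_populations.py   # ANOVA ranking + Ward tree
python analysis/03_build_signature.py        # markers, M grid, signature
python analysis/04_deconvolve_and_score.py   # 4 cohorts, fractions, STEM
python analysis/05_survival_analysis.py      # cutoff, subtypes, Cox, meta
```

Step 02 reports the population cut and its stability across the top-N gene
grid; on the shipped configuration it assigns ten populations
(Stromal 270 cells, EMEC 180, PMEC 150, …). Step 03 prints the
marker-depth table and builds a 678-gene × 10-population signature. Step 05
ends with (abridged):

```
trainGC optimal STEM cutoff: 6.254 (quantile 0.71, p = 3.68e-12)
trainGC: multivariate STEM HR = 0.884 (0.853-0.915), p = 4.79e-12
meta-analysis STEM: pooled HR = 0.893 (0.879-0.906), p = 4.84e-49
TME subtyping: k = 3 fixed (validity-index panel suggests k = 2); counts: {'TMEsubtype-M': 716, 'TMEsubtype-L': 370, 'TMEsubtype-H': 254}
subtype survival separation: log-rank chi2 = 176.15, p = 5.63e-39
Stromal marker screen (risk): 40/40 genes selected at meta p < 1e-5
```

Reading: the fitted multivariate hazard ratio per STEM unit (0.884–0.897
across cohorts) recovers the planted protective effect (HR ≈ 0.90); the
pooled fixed-effects estimate sharpens it; the stroma/monocyte-rich
TMEsubtype-H is the smallest and worst-prognosis group; and stromal marker
genes are uniformly risk-associated, as their fractions track the hazard.

Library usage mirrors the drivers, e.g.:

```python
from gctme import synthetic, sc_preprocess, signature
from gctme.deconvolution import DeconvConfig, deconvolve

adata, markers = synthetic.simulate_sc_dataset(synthetic.SimScConfig(seed=1))
pb = sc_preprocess.tpm_normalize(
    sc_preprocess.pseudobulk_summarize(sc_preprocess.qc_filter(adata))
)
sel, stats = signature.select_markers(pb)
sig = signature.build_signature(pb, sel)
```

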