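# epilnc

Immune subtyping of tumors from **lncRNA promoter methylation**, with
detection of epigenetically regulated (ER) lncRNAs and their links to
the tumor immune microenvironment.

The package is aimed at computational epigenomics groups working with
paired 450K-style DNA methylation and RNA-seq profiles of a tumor
cohort (the motivating setting is diffuse glioma). It implements, as a
tested and reusable pipeline, the chain of analyses that takes
probe-level beta values to immune-relevant lncRNA candidates:

1. **Promoter methylation** — probe betas averaged over 4-kb windows
   centered on each gene's TSS (`io_annotation`), plus chromatin-state
   summaries over ChromHMM-style segmentations.
2. **Subtype discovery** — the top-5% most variable lncRNA promoters
   feed resampling-based consensus clustering (1000 iterations, 0.8
   subsampling); the cluster number is chosen by the PAC criterion
   (`subtype`). The cluster with higher immune-cell infiltration is the
   immune-**Hot** subtype.
3. **ER lncRNAs** — differentially methylated between subtypes
   (Wilcoxon rank-sum, |Δβ| > 0.2, BH-FDR < 0.05) *and* negatively
   correlated with their own expression (`er`):

   `is_er ⇔ |Δβ| > 0.2 ∧ FDR < 0.05 ∧ r(β, expr) < 0 ∧ p_r < 0.05`

4. **Immune scoring** (`immune`) — per-sample ssGSEA signature activity
   (rank-weighted ECDF difference), CYT = √(GZMA·PRF1) on the linear
   scale, MHC-I mean expression, an ESTIMATE-like purity surrogate,
   Wilcoxon differential expression (|logFC| > 0.75, FDR < 0.05), the
   opposite-direction infiltration filter, and the ImmLnc-style
   association: genes ranked by partial correlation with a lncRNA given
   tumor purity, scored against immune pathways by weighted-KS GSEA
   with a gene-label permutation null.
5. **Survival** (`survival`) — Kaplan–Meier, log-rank, Cox proportional
   hazards (Efron ties), a likelihood-ratio ladder
   (LR = 2·[ℓ(base+f) − ℓ(base)], χ² test) over an age+gender base
   model, stepwise-AIC Cox selection, TMB (mutations/40 Mb) and
   hypergeometric subtype enrichment.
6. **Evasion** (`evasion`) — correlations with immunosuppressive
   markers, responder vs non-responder tests, and methylation vs
   expression as median-split prognostic readouts.

Because these analyses are usually exercised on controlled downloads,
the package ships a first-class **synthetic cohort generator**
(`synthetic`) that plants two immune subtypes, ER lncRNAs with negative
methylation–expression coupling, infiltration gradients and
subtype-linked survival — so every stage can be validated against known
ground truth without any external data.

## Worked example

The numbered scripts under `analysis/` run the full study on the
default synthetic cohort (300 samples, 1000 lncRNAs, 1200 PCGs, 50
planted ER lncRNAs):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_subtype_discovery.py
python analysis/03_er_lncrnas.py
python analysis/04_immune_landscape.py
python analysis/05_survival_models.py
python analysis/06_immune_evasion.py
```

which prints, among other things:

```
chosen k = 2 (PAC 0.000); cluster sizes {1: 150, 2: 150}; cluster 1 is the immune-hot subtype
1000 lncRNAs tested, 50 called ER
50/50 are hypomethylated in the immune-hot cluster (median dbeta -0.299,
median methylation-expression r -0.593)
277 of 1200 PCGs differentially expressed (|logFC| > 0.75, FDR < 0.05)
log-rank subtype 1 vs 2: chi2 = 29.05, p = 7.04e-08
stepwise-AIC Cox selected: subtype (AIC 1957.0)
methylation beats expression as a prognostic split for 50/50 immune lncRNAs
```

Read: consensus clustering recovers exactly the two planted subtypes
(PAC = 0 means no ambiguous consensus entries); all 50 planted ER
lncRNAs are recalled with no false positives, all hypomethylated in the
Hot cluster; the Hot subtype shows higher immune pathway activity,
cytolytic score and mutational burden, and markedly worse survival; and
promoter methylation is the stronger prognostic readout of the two
levels, as the planted hazard structure dictates.

The same pipeline is available end-to-end from a single entry point:

```sh
epilnc simulate --out cohort/ --seed 101
epilnc run --input-dir cohort/ --out out/ --seed 7   # writes out/report.json
```

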