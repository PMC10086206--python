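# Methods

This note documents the models, conventions and design choices behind
`epilnc`, in the order the pipeline runs them.

## Coordinate and interval conventions

All interval membership in the package is half-open `[start, end)`, on
1-based positions, and inputs are assumed to share one genome build
(coordinate conversion is out of scope). A gene's promoter is the 4-kb
window `[tss − 2000, tss + 2000)` centered on its strand-resolved TSS;
a probe may serve several overlapping promoters (no exclusivity rule is
applied, including promoters shared by a lncRNA and a protein-coding
gene). Promoter methylation is the arithmetic mean of the non-missing
probe betas in the window; a gene–sample cell is missing only when all
its probes are missing. Chromatin-state summaries follow the same
conventions over 18-state ChromHMM-style segmentations (E01–E18).

## Subtype discovery

Features are lncRNA promoters ranked by cross-sample standard deviation
(missing values ignored); the top `ceil(0.05·n)` are kept, with ties at
the cutoff broken lexicographically by gene id so selection is
deterministic.

Consensus clustering follows the resampling scheme of
ConsensusClusterPlus: each of `n_iter` iterations (default 1000)
subsamples `floor(0.8·n)` samples without replacement, clusters them,
and the consensus entry for a sample pair is its co-clustering count
divided by its co-sampling count. Subsampling uses a counter-based
stream — iteration *i* is seeded by `(seed, i)` — so increasing
`n_iter` never reshuffles earlier iterations, and the whole stage is a
pure function of its seed.

**Inner clustering is agglomerative average linkage on Euclidean
distance over beta values.** We deliberately do not use a
profile-shape metric (1 − Pearson): between immune subtypes the
methylation signal is a predominantly one-directional shift shared by
the selected promoters (hypo- vs hypermethylation), i.e. close to a
constant offset of the whole profile. Correlation distance centers
each sample profile and is therefore mathematically blind to exactly
this structure; Euclidean distance sees it directly. Missing feature
values are mean-imputed per feature before distances are computed.

Final labels come from average-linkage hierarchical clustering of
`1 − consensus` cut at *k*. The number of clusters is chosen by the PAC
criterion — the fraction of off-diagonal consensus entries in
(0.1, 0.9) — with ties resolved toward the smallest *k*. Clusters must
retain strictly more than 5 samples; smaller clusters' members are
marked unassigned and excluded downstream. The retained cluster with
the highest mean immune-cell infiltration is relabeled cluster 1
("Hot"); all Δβ and logFC sign conventions are cluster 1 − cluster 2.

## ER lncRNA detection

Differential methylation uses the two-sided Wilcoxon rank-sum test:
exact enumeration when both groups have ≤ 8 observations and no ties,
otherwise the normal approximation with tie and continuity correction.
Features need ≥ 3 non-missing values per group to be tested.
Benjamini–Hochberg correction runs across all tested lncRNAs. An ER
call additionally requires a negative cohort-wide Pearson correlation
between promoter beta and log2 expression with p < 0.05 (the
correlation is computed over all assigned samples pooled, not within
clusters). Requiring the correlation p-value, not just the sign, is
configurable (`require_corr_p`).

## Immune scoring

*ssGSEA.* Genes are ranked by expression descending (ties broken by
gene id); position *i* from the top carries absolute rank value
`n − i`. The score is `Σ_i [P_in(i) − P_out(i)]` where `P_in` is the
ECDF of in-set genes weighted by `rank^0.25` and `P_out` the unweighted
ECDF of out-of-set genes. Using rank-derived weights (rather than raw
expression) makes scores invariant to any strictly monotone transform
of the expression values.

*CYT* is the geometric mean of GZMA and PRF1 on the linear scale
(`2^x − 1` back-transform, pseudocount 0.01 against zeros). *MHC* is
the mean log2 expression of the MHC-I set. The *ESTIMATE-like* score is
the sum of stromal and immune ssGSEA components — a like-for-like
purity surrogate, not the published fitted coefficients; the purity
control variable used downstream is 1 minus the min–max-scaled
combined score unless a purity vector is supplied.

*Differential expression* is Wilcoxon + log2 fold change with the
|logFC| > 0.75, FDR < 0.05 thresholds — a deliberate nonparametric
engine recorded in the pipeline report metadata.

*Immune-related lncRNAs.* Per (lncRNA, cell type), Pearson correlations
are computed at the expression and methylation levels; BH-FDR runs
across the full pair grid within each level, and a pair passes only
when both q < 0.05 and the correlation signs are strictly opposite. The
pipeline calls a lncRNA immune-related when ≥ 4 of the 6 cell types
pass.

*Pathway association.* Protein-coding genes are ranked by first-order
partial correlation with the lncRNA controlling for purity,
`(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))`, descending, ranking by the
coefficient itself. Each pathway is scored by a weighted
Kolmogorov–Smirnov running sum (hit increments ∝ |weight|, miss
decrement `1/(n−|S|)`; ES is the signed extremum). The null permutes
gene labels (equivalently, draws random hit sets of the same size) with
`n_perm` draws; p-values are add-one smoothed,
`(1 + #{|ES_null| ≥ |ES|})/(n_perm + 1)`, and BH-corrected across
pathways. NES divides ES by the mean |ES| of same-signed null draws.
Note that this null is competitive: when a large fraction of the
background is co-regulated with the lncRNA, sets of genuinely
independent genes appear *depleted* (negative ES), which is the correct
behavior of the statistic, not an error.

## Survival

Kaplan–Meier and Cox fits are delegated to lifelines; ties are handled
by the Efron method, and subjects censored at *t* remain at risk for
events at *t*. The covariate-free partial log-likelihood used as the
stepwise starting point is computed in closed form
(`−Σ_t Σ_{j<d_t} log(r_t − j)`), which matches lifelines'
likelihood-ratio test exactly. The LR ladder adds each candidate
feature alone to a fixed age+gender base model (features are added
"respectively", not cumulatively); a candidate that does not increase
the rank of the design matrix — e.g. a duplicated covariate —
contributes exactly LR = 0 rather than attempting a degenerate fit.
Stepwise selection is bidirectional on AIC with ties broken by feature
name; note that with *k* pure-noise candidates the best one clears the
AIC penalty with probability `1 − P(χ²₁ < 2)^k`, so occasional noise
selections are expected behavior of the criterion. Categorical
covariates are dummy-encoded with sorted levels, first level dropped.
TMB is mutations per 40 Mb. Continuous scores are dichotomized at the
median wherever a KM split is needed; optimal-cutpoint scanning is
deliberately avoided because it inflates type-I error.

## Synthetic cohort

The generator is a pure function of its config (one master RNG; the
pipeline fans its own master seed out to stages by hashing stage
names). Defaults: 300 samples in two equal subtypes, 1000 lncRNAs and
1200 PCGs tiled 10 kb apart on 22 chromosomes, 2–8 probes per promoter.

- **Methylation**: gene-level betas are Beta-distributed with precision
  60, parameterized by mean; ER lncRNAs (5% of lncRNAs) and a subset of
  immune marker genes have their Hot-subtype mean lowered by
  `delta_beta_effect` (default 0.3, Cold means drawn from U(0.5,
  0.75)). Probe betas jitter around the gene value (σ = 0.03, clipped
  to [0, 1]).
- **Expression** (log2 scale, clipped at 0): for ER lncRNAs the signal
  is `2 + 4·(1 − β)` plus, for immune lncRNAs, a latent per-sample
  immune activity; Gaussian noise is calibrated per gene so the
  realized methylation–expression Pearson correlation matches
  `meth_expr_rho` (default −0.6). Immune pathway, signature, MHC-I and
  marker genes load on the latent activity scaled by
  `infiltration_shift`; stromal genes load on an independent latent.
- **Infiltration**: six TIMER-style cell fractions, each
  `base + w·shift·activity + noise`, clipped at 0.
- **Survival**: exponential with Cold median 24 months and hazard ratio
  `hazard_ratio_hot` (default 2) for Hot; independent uniform censoring
  whose upper bound is solved numerically for a 30% censored fraction.
- **Response**: responder probability decreases logistically with the
  immune activity, so immune lncRNA expression is decreased in
  responders.
- Setting `delta_beta_effect`, `meth_expr_rho`, `infiltration_shift`
  to 0 and `hazard_ratio_hot` to 1 yields the null configuration used
  for false-positive calibration.

What the generator does **not** emulate: realistic probe-level
covariance along the genome, cell-type deconvolution error, copy
number, batch effects, non-proportional hazards, or any coupling
between expression and methylation beyond the planted linear one.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated generative assumptions, not
performance on real tumor data. One visible consequence: because the
subtype drives methylation, expression, infiltration and survival
jointly, *all* ER lncRNAs — not only the explicitly immune-coupled
subset — pass the infiltration filter on synthetic data.

## Problem sizes and numerical tolerances

Recovery checks run at n = 300 samples with 200 consensus iterations
over k ∈ {2..6}, 1000-permutation pathway association, and 50
repetitions of n = 1000 Cox cohorts; brute-force oracle equivalence
(ssGSEA, GSEA running sum, BH step-up, product-limit estimator, partial
correlation) is checked on ≥ 200 random small instances per operation
at 1e-9 absolute tolerance (1e-6 for KM products). Collinearity guards
treat |r| within 1e-12 of 1 as degenerate; LR statistics are
non-negative up to 1e-6. Stage outputs, including the pipeline's
`report.json`, are byte-identical across reruns with the same seed.
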