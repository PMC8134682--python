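# Methods

`iciscope` characterizes the immune microenvironment of bulk tumor
expression cohorts and condenses it into a single prognostic statistic, the
immune-cell-infiltration (ICI) score. This note documents the models and
procedures each module implements, the defaults and why they were chosen,
what the synthetic cohorts do and do not emulate, and the numerical choices
that matter for reproducibility.

## Pipeline overview

1. **Deconvolution.** Per-sample immune-cell fractions are estimated by
   nu-support-vector regression of each bulk profile against a cell-type
   signature matrix; immune and stromal activity are scored by single-sample
   gene-set enrichment (ssGSEA).
2. **ICI subtypes.** Cell-fraction profiles are consensus-clustered
   (resampled hierarchical clustering) into immune subtypes.
3. **Signature discovery.** Differentially expressed genes (DEGs) among the
   subtypes are found with an empirical-Bayes moderated t; samples are
   re-clustered on DEG expression into gene clusters; each DEG joins
   signature A or B by the sign of its association with the immune-ordered
   cluster axis; a shadow-feature random-forest pass (Boruta) prunes
   uninformative genes.
4. **Scoring.** Each signature block is summarized by the first principal
   component of its z-scored expression, projected to samples;
   `ICI score = PC1(A) − PC1(B)`.
5. **Evaluation.** A maximally selected log-rank cutoff splits the cohort
   into high/low score groups, which feed Kaplan–Meier/log-rank/Cox
   survival analysis, mutation-frequency contrasts and TMB correlation,
   preranked GSEA, and therapy-response ROC and rate tables.

## Deconvolution

The nu-SVR deconvolution follows the CIBERSORT algorithm. The signature
matrix is standardized globally (one mean/sd over all entries) and each bulk
column per sample, which makes fractions invariant to positive rescaling of
a bulk profile. A linear-kernel `NuSVR` (C = 1) is fitted at
nu ∈ {0.25, 0.5, 0.75}; negative coefficients are clipped to zero and
renormalized to sum 1; the nu with the smallest RMSE between the clipped
reconstruction and the standardized bulk vector wins. An optional
permutation p-value shuffles the bulk vector's gene labels and reports the
fraction of permutations whose best-fit reconstruction correlation reaches
the observed one (default off, `n_permutations = 0`, because it multiplies
runtime by the permutation count). Quantile normalization of the mixture is
available but off by default — it belongs to the array-era workflow and is
unnecessary for the TPM-like inputs the package targets.

No reference signature ships with the package; any matrix with marker genes
in rows and cell types in columns can be supplied as TSV. Tests and
examples use a 22-type synthetic analogue with block-structured markers.

The ssGSEA score walks each sample's expression ranking from the top and
accumulates the difference between a weighted in-set ECDF (weights
rank^alpha, alpha = 0.25, the conventional exponent) and the unweighted
out-of-set ECDF, summed over all positions. Being rank-based it is
invariant to any strictly monotone transform of expression. The ESTIMATE-
style combined score is the sum of the immune-set and stromal-set scores.

## Consensus clustering

For each candidate k (default 2–6), items are subsampled without
replacement (80%) and clustered `reps` times (default 1000 for analysis;
100–200 in tests and the pipeline default, which is already stable for
well-separated structure). The base clusterer is hierarchical with
Euclidean distance and Ward linkage; k-means is available. The consensus
entry for a pair is the fraction of co-clustered runs among runs where both
were sampled; never-co-sampled pairs are flagged explicitly rather than
silently zeroed. Final labels at each k come from average-linkage
clustering of (1 − consensus).

**Choosing k.** The area A(k) under the CDF of consensus values equals
1 − mean(consensus) and grows as structure stabilizes. The delta-area curve
is Δ(2) = A(2) and Δ(k) = (A(k) − A(k−1))/A(k−1) for k > 2. Taking the raw
argmax of Δ is biased to k = 2 on balanced data, because Δ(2) is an absolute
area rather than a change: on planted three-cluster data Δ(2) ≈ 0.47 always
exceeds Δ(3) ≈ 0.43. The package therefore selects the k at which the
delta-area curve collapses — the argmax of Δ(k)/Δ(k+1) — which recovers the
planted k on balanced 2-, 3- and 4-cluster fixtures across seeds. The
pipeline nonetheless pins k = 3 for both ICI and gene clusters, the
standard choice for the three melanoma immune phenotypes (inflamed,
desert, excluded); `chosen_k` is reported alongside for diagnostics.

Cluster labels are canonicalized A, B, C… by descending mean immune score,
so "cluster A" is reproducibly the most immune-infiltrated subtype. The
input to ICI clustering is the cell-fraction table alone by default;
immune/stromal scores can be appended as extra (z-scored) features.

## Differential expression

Per gene, a one-vs-rest two-sample contrast on log2-scale expression gives
log2 fold change and a pooled residual variance s_g² on d_g = n − 2 df. The
variance prior (d0, s0²) is fitted by moment matching on log s_g² using
digamma/trigamma moments (the standard empirical-Bayes scheme for
microarray-scale data); the posterior variance
s̃² = (d0·s0² + d_g·s_g²)/(d0 + d_g) yields a moderated t on d0 + d_g df.
Genes with zero pooled variance never divide by zero — shrinkage keeps the
posterior variance positive — and a gene constant everywhere reports p = 1.
When the observed log-variances underdisperse relative to the chi-square
expectation, d0 = ∞ and the statistic degrades gracefully to a z-score with
the common prior variance.

DEG selection runs the contrast once per cluster (one-vs-rest, so three
contrasts at k = 3), adjusts p per contrast by Benjamini–Hochberg, and
takes the union of genes passing |log2 FC| > 1 and adjusted p < 0.05 in at
least one contrast, keeping each gene's best contrast. The fold-change
threshold is interpreted on the log2 scale (a 2-fold change), the
conventional reading; `fc_scale="linear"` switches the interpretation for
cohorts where the threshold was meant as a linear fold change.

## Signatures and the ICI score

Gene clusters are ordered by ascending mean immune score; each DEG's
Spearman correlation between expression and that ordered rank assigns it to
signature A (positive) or B (negative); |rho| below 1e-12 (e.g. constant
genes) is excluded rather than forced. The Boruta pass appends a shuffled
shadow copy of every feature, fits a random forest against the gene-cluster
label, counts "hits" where a real feature beats the best shadow, and
confirms/rejects by a two-sided binomial test against Binomial(n_iter, ½)
with BH correction; only confirmed genes are kept by default.

PC1 scoring z-scores each gene across samples and projects the first right
singular vector of the gene × sample matrix onto samples. A principal axis
has no intrinsic sign, so the score is anchored to correlate positively
with the block's mean z-scored expression; a one-gene block degrades to
that gene's z-profile. The ICI score is PC1(A) − PC1(B) per sample; an
empty signature contributes zero with a warning.

## Survival analysis

Kaplan–Meier estimation and the k-group log-rank test use the standard
product-limit and hypergeometric-variance forms (via lifelines). The score
cutoff maximizes the standardized two-group log-rank statistic |z| over
midpoints between consecutive distinct scores, subject to both groups
holding at least `min_group_fraction` (default 0.1) of the cohort; ties
resolve to the lower cutoff. No multiplicity-adjusted p-value is attached
to the selected cutoff — the cutoff is used for grouping and downstream
tests are reported as-is. Hazard ratios come from a single-covariate Cox
partial likelihood maximized by Newton–Raphson with Breslow tie handling
(ties are rare at the event-time resolution simulated); a group with no
events triggers a monotone-likelihood flag with an unbounded CI rather
than a spurious estimate. Stratified forest tables run the same fit within
user-defined strata, skipping strata under 10 samples.

## Mutations, enrichment, response

TMB is the per-sample count of records in the conventional non-synonymous
MAF classification set; samples missing from the MAF count zero, and the
high/low TMB split defaults to the cohort median. Per-gene 2×2
(wild/mutant × high/low) contrasts use the Pearson chi-square **with Yates
continuity correction** — verified against a published 50-gene melanoma
driver table (197 high / 250 low samples) shipped as package data, all of
whose printed p-values reproduce to at least three significant figures.
Frequency tables rank genes by overall mutated fraction (ties
alphabetical) and collapse ≥2 records of one gene in one sample to
"Multi_Hit".

Preranked GSEA uses the weighted running-sum with hit increments
∝ |metric|^weight (weight 1) and gene-label permutation as the null;
nominal p uses same-sign null values with an add-one correction, NES
normalizes by the mean same-sign |null ES|, and FDR q follows the pooled
positive/negative null procedure. The ranking metric for high-vs-low score
contrasts is the moderated t. Over-representation is the upper-tail
hypergeometric against a user universe with BH adjustment. No ontology or
MSigDB content ships with the package.

ROC/AUC uses the rank (Mann–Whitney) formulation with tie correction;
response dichotomization follows RECIST (CR/PR responders vs SD/PD).

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, so every
stage can be scored against ground truth:

- **Signature matrix**: block markers (10 per type, 22 types by default) at
  expression level 100 over background 1, with log-normal jitter (sd 0.1).
- **Mixtures**: fractions per sample drawn from subtype-specific Dirichlet
  concentrations — subtype A (inflamed) up-weights CD8 T, activated NK,
  activated CD4 memory and Tfh; B (desert) up-weights M0, activated mast
  and resting NK; C (excluded) up-weights B cells, Tregs, M1 and M2. Bulk
  columns are signature · fractions with gene-wise multiplicative
  log-normal noise (sd 0.2 by default).
- **Latent axis**: the summed fraction of the four inflamed effector types
  defines per-sample immune activity; M1 is deliberately not part of it
  because it marks the excluded phenotype.
- **Survival**: exponential event times with hazard
  baseline · exp(log HR · z-scored activity), default log HR −0.7, so
  proportional hazards hold exactly and Cox recovery is unbiased.
  Censoring is independent Uniform(0, τ) with τ solved so the expected
  censored fraction hits the target (default 0.3).
- **Mutations**: per-sample non-synonymous burden ~ Poisson (mean 35 in the
  immune-low half vs 25 in the immune-high half) plus driver genes with
  2.5-fold higher mutation odds in the immune-low half, echoing the
  negative infiltration/burden association reported in melanoma.
- **Response**: CR/PR/SD/PD from a proportional-odds model on the z-scored
  activity (slope 1.5).

What the generator does **not** emulate: gene–gene correlation beyond the
shared cell-type structure, platform/batch effects, compositional artifacts
of real deconvolution references (collinear cell types), non-proportional
hazards, and clinical covariates correlated with immune content. Passing
recovery tests therefore demonstrates correctness of the machinery under
the stated model, not performance on any real cohort.

## Problem sizes and defaults

The default pipeline cohort is 300 samples × 220 genes with consensus
`reps = 200` and 50 Boruta iterations (~45 s on one core). Recovery
experiments that repeat the pipeline across 10 seeds use 150-sample
cohorts with `reps = 60` and 20 Boruta iterations, which preserves every
stage while keeping a 10-seed sweep under three minutes. Consensus
recovery fixtures use 60 items; oracle comparisons (exhaustive cutoff
search, Cox likelihood grid at 1e-4 resolution, AUC pair counting,
hypergeometric enumeration) use ≤ 200 subjects where exhaustive computation
is exact.

## Known limitations

- The nu-SVR deconvolution underfits when very few marker genes are
  available (tens of genes); with realistic marker counts (≥ 100 genes for
  22 types) it matches constrained least squares to < 0.01 per fraction.
- The delta-area elbow needs at least three candidate k values; with a
  two-value range it reduces to comparing two deltas.
- The Cox implementation is univariate by design (group contrasts and
  stratified forests); multivariable adjustment is out of scope.
- GSEA FDR uses the pooled-null approximation; for very few sets the q
  estimate is coarse, and the nominal p is the better-calibrated quantity.
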