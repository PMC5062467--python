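# Methods

This note documents the statistical models, the default parameters and the
numerical choices behind `pancanmet`, and what the synthetic study
conditions can and cannot demonstrate.

## Differential expression (NB Wald)

Counts are modelled per gene as negative binomial with variance
μ + αμ². The design is intercept + group with log size-factor offsets;
size factors are median-of-ratios against the per-gene geometric-mean
reference (the median is taken over the ratios themselves). Samples whose
counts share no all-positive gene cannot be normalized this way; the
`pseudo_reference` option switches to a log(count + 0.5) reference.

Dispersion estimation follows the standard shrinkage recipe for small-n
RNA-seq designs:

1. gene-wise maximum likelihood with a Cox–Reid adjustment
   (−½ log det XᵀWX) to reduce the small-sample downward bias, bounded to
   [1e-8, 30];
2. a parametric trend α(μ) = a₀ + a₁/μ fitted by gamma-weighted iteratively
   reweighted least squares with 10⁴-fold outlier exclusion;
3. moderation of the gene-wise estimates toward the trend under a log-normal
   prior whose variance is the MAD² of the log residuals minus the expected
   sampling variance (trigamma((n−p)/2)), floored at 0.25. The posterior
   mode is found by vectorised golden-section search on log α — the
   penalised likelihood has no closed-form maximiser, so "posterior mode
   under the log-normal prior" is computed numerically.
   Genes whose gene-wise estimate sits far above the trend keep it
   (dispersion outliers). `dispersion="gene-wise-only"` disables steps 2–3.

The Wald statistic is the group coefficient over its standard error from the
expected information; p-values are two-sided normal, BH-adjusted with
all-zero genes excluded. On a 200-gene fixture the whole path agrees with an
independently developed NB Wald implementation (pydeseq2) to correlation
&gt; 0.999 and log2FC within 0.05; at α → 0 it collapses onto the Poisson GLM
Wald statistic to &lt; 1%.

One deliberate approximation is documented by a test: multiplying one
sample's raw counts by c multiplies its relative size factor by c exactly,
but the Wald statistics move slightly (≈0.1 at c = 3 on a 200-gene fixture)
because scaling raw counts changes the likelihood weighting, not only the
offset. Exact invariance would hold only if depth entered purely through the
offset.

The continuous-expression path (validation cohorts) records a Shapiro–Wilk
p-value per gene on group-centred residuals as a QC field and always
proceeds to a two-sided Welch t-test: the unequal-variance form was chosen
because pooling is never safe by default and the two coincide for balanced
groups with equal variances. No branch is taken on the normality outcome;
the QC column lets users filter afterwards.

## Promiscuity correction

Promiscuity is the number of pathways containing a gene (≥ 1). The
correction divides the gene-level statistic by it, exactly preserving sign
and leaving single-pathway genes untouched; genes absent from the signature
are dropped (counted in the log) because the analysis concerns metabolic
genes only. Gene matching is exact string match after whitespace trimming —
alias resolution is data curation, out of scope. The GMT file (Broad
dialect) is the single signature interchange format.

## GSEA

The enrichment score is the classic weighted running sum with default
weight 1 (configurable in {0, 1, 1.5, 2}); ranking ties are broken by gene
identifier so results are deterministic. The null permutes gene labels, not
samples, because the pipeline receives precomputed statistics; one seed
derives a single permutation block shared by all pathways, which makes
pathway p-values comparable and the whole result reproducible. Permutations
are drawn against a canonical (sorted) gene ordering, which has a useful
consequence: negating every statistic maps each null ES to its negative
exactly, so up and down p-values swap exactly under a sign flip.

Directional p-values use the plus-one estimator (never zero; floor
1/(n_perm+1)); n_perm &lt; 100 is rejected as an unstable tail, and the
default is 1000. With m pathways the smallest attainable BH q is
m/(n_perm+1) — at the default 60 pathways and 1000 permutations that is
0.06… below 0.05 only for the pathways ranked first; analyses with many
pathways should raise n_perm accordingly. Set sizes outside [5, 500] after
intersection with the universe are skipped with a log entry. Mixed-
directional statistics and leading-edge reporting are not implemented.

## Rewiring scores

The variance-stabilizing transformation uses the closed form implied by the
fitted trend: with variance (1+a₁)q + a₀q², u(q) =
(2/√a₀)·asinh(√(a₀q/(1+a₁))) applied to size-factor-normalized counts —
monotone, √-like at small a₀ and log-like at large q. When the trend cannot
be fitted (too few usable genes) the fallback is log2(q+1), tagged
`shifted-log` in the provenance field and loudly logged.

The fold change r is computed literally as a ratio of VST-scale tissue
means over the unweighted mean across tissues (so mean_t r = 1 per gene,
an identity the tests check to 1e-12), although the VST scale is log-like;
this fidelity-first choice keeps the printed algebra intact, and the
normal/cancer comparison is unaffected because both compartments are
treated identically. The focal tissue is included in the average. Pathway
scores are plain means of r over pathway genes; Spearman correlation of
N_p vs C_p per matched tissue pair (≥ 5 shared pathways) and per-tissue
sample SD of the scores complete the picture.

Classification compares each pathway's enrichment status in a normal tissue
(vs the pooled other normals) with its change in the matched cancer (vs that
normal), both at BH q &lt; 0.05 from the GSEA module: a flip normal-up →
cancer-down is "lost", normal-down → cancer-up is "gained", any other
outcome for a pathway significant in normal is "maintained", and pathways
not significant in normal are "unchanged". Only the lost/maintained cases
are pinned by the upstream description; the rest is this package's reading
of "and vice versa", and the summary fractions are reported within each
normal-status stratum so they partition to 1. A tissue-independent summary
counts pathways changed in &gt; 20% of cancers.

## Survival stratification

Times are days/365.25 (configurable); death time is authoritative for dead
patients. The threshold is the linear-interpolation (type-7) quantile of
*all* patients' observed times — the common default, not specified upstream;
the published worked example (total follow-up 10.93 y, threshold 1.62 y)
rules out a fraction-of-maximum reading. Membership is strict
(&gt; / &lt;); patients exactly at the threshold are excluded with reason
"boundary", as are alive-short-followup and dead-late patients and those
with missing status or time. Cohorts with fewer than 5 patients in either
group are dropped.

## Clustering

PAM is implemented directly (no pre-installed k-medoids exists): greedy
BUILD initialization, then best-improvement SWAP; ties break toward the
lowest sample index, so the algorithm is fully deterministic and the final
configuration is single-swap optimal (tests audit this exhaustively). The
gap statistic uses uniform reference draws over each feature's observed
range (zero-range features pass through unchanged), B = 50 references by
default, and the 1-SE rule. Within one gap call the cost curve is kept
non-increasing in k by also warm-starting each k from the previous medoid
set plus its best addition. Distances are unscaled Euclidean on pathway
scores (a z-score option exists); whether the original analysis scaled is
unknown, so unscaled is the default. Tissue enrichment is the upper-tail
hypergeometric probability per (cluster, type) with BH across all pairs.

## Essentiality

Lower score = more essential (ATARIS convention; a flag inverts). Top-5%
calls are per cell line over non-NA genes, floor(fraction·n) genes, ties
broken by identifier. Tissue essential sets are unions over the tissue's
cell lines; occurrence counts tissues, and pathway values average occurrence
over the pathway's scored genes. The ANOVA is one-way (score ~ tissue) per
gene, computed vectorised, BH across testable genes.

## Synthetic study conditions

The generator emulates the statistical structure each stage assumes, with
defaults chosen to be desk-scale yet realistic for bulk RNA-seq: 2000 genes
(60 pathways × 20 genes metabolic, the rest background), 20% promiscuous
genes with one extra membership, log-normal baseline means (ln-mean 4.0,
ln-sd 1.5, i.e. median ≈ 55 counts), dispersion trend α(μ) = 0.05 + 2/μ,
log-normal library sizes (ln-sd 0.2), planted pathway effects of |log2FC|
1–1.5, 20+20 samples per tissue; clinical tables with exponential death
times (mean 1 y) for half the patients and uniform censoring to 10 y;
essentiality matrices with 3-SD tissue shifts on 50 genes; metabolites
linearly coupled to pathway means. Counts are gamma-Poisson draws
(variance μ + αμ², verified against the NB moments to 5%), a gene in
several planted pathways takes the largest-magnitude effect, and every
stream is sub-seeded from one seed, so outputs are bit-identical per seed.

What passing on these conditions does **not** show: robustness to
gene-length/GC bias, batch effects, outlier samples, alias mismatches
between expression and signature, or the scale of real TCGA cohorts (the
published pan-cancer numbers require the original downloads and are out of
reach at desk scale). The tests demonstrate correctness of the algebra and
calibration of the inference under the stated model, not performance on
real data.

## Problem sizes used in the checks

The shipped verification runs use 2000-gene cohorts with 10–20 samples per
group, 50-seed repetitions for the stochastic recovery claims, 1000
permutations for GSEA calls, B = 10–50 gap references, and 100-seed ANOVA
power runs — sizes chosen so the whole suite completes in about a minute
while leaving the statistical margins (≥ 90–95% recovery bars, binomial
confidence bands) comfortably wide.
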