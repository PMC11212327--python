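# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind each pipeline stage, and states what the
synthetic cohorts do and do not emulate.

## Synthetic cohorts

The generator produces every input the pipeline consumes — three
per-tumor caller VCFs, a pooled-normal VCF, annotation/role tables, a
gene × sample count matrix, gene sets and a clinical table — plus a
ground-truth JSON for recovery checks. All randomness flows from one
seed through independent per-concern streams (variants, callers,
expression, survival, clinical), so adding tumors never perturbs the
expression or survival draws, and identical configs give byte-identical
files.

**Clonal architecture.** Each tumor carries a trunk (CCF 1 in
cancer-cell space) plus 0–3 subclonal branches. With probability
`p_branched` (default 0.5) the tumor receives ≥ 2 sibling branches
whose CCFs sum to ≤ 0.92 with pairwise separation ≥ `min_ccf_sep`
(default 0.25); otherwise 0 or 1 subclone. Sibling-only planting is
deliberate: single-sample CCF data cannot distinguish a nested chain
(trunk→A→B) from siblings (trunk→{A,B}) whenever B's CCF fits under
A's, so the generator plants only architectures that are identifiable
under the tree builder's pigeonhole convention (below). The default
separation of 0.25 reflects what is resolvable at the default depth:
at 225× and purity ~0.65, binomial read sampling alone contributes
≈ 0.09 CCF standard deviation on top of the planted per-mutation
jitter (`ccf_sd` = 0.05).

**Variants.** Passenger counts are Poisson with mean 285 per tumor
(the scale of an exome at ~5.7 mutations/Mb); half sit on the trunk,
the rest split across subclones. Per-variant CCF is Gaussian around
the cluster CCF, clipped to [0.02, 1.2] — the upper clip matches the
downstream CCF cap rather than 1.0, because clipping at 1.0 creates a
point mass that a Gaussian mixture resolves into a spurious cluster.
Driver genes are planted by prevalence (TP53 0.57, KRAS 0.28, MET
0.14), with MET exon-14 skipping (represented as a splice-consequence
variant, annotated as a curated pathogenic protein-altering event)
mutually exclusive with TP53/KRAS. Drivers sit on the trunk with
probability 0.8. TP53 occasionally (p = 0.05) receives a second
distinct hit, the convergent-evolution signature. TP53's role is
"both" (tumor suppressor and oncogene-like), so its pathogenic
missense mutations qualify as drivers alongside truncating events;
with a pure-TSG role the curation rules would silently drop the most
common real TP53 drivers.

**Caller model.** Each caller reports a true variant with its
sensitivity (defaults 0.93–0.97), adds Poisson false positives at
`fp_rate_per_mb × target_mb` (unique loci per cohort, so false
positives never reach caller consensus), and with a small probability
(0.02–0.03) collapses a variant's alternate reads onto one strand —
the artifact the strand-VAF filter exists to remove. Depths are
binomial around 225 per locus (split per strand), and
VAF = CCF × purity / 2 for diploid heterozygous sites; copy-number
effects on VAF are not simulated, which keeps CCF recovery
analytically checkable. A configurable number of recurrent artifact
loci appear in every tumor at germline-like VAF and in the pooled
normal, exercising the pooled-normal subtraction.

**Expression.** Negative-binomial counts (dispersion 0.3, baseline
mean 100) over 5,000 genes with lognormal gene-intrinsic abundance
(σ = 0.6 on the natural log). The immune signature (100 genes) and a
neutrophil marker set (10) are multiplied by 2^2 in Immune-High
samples; the stromal signature (50) gets half the log-effect. Library
sizes span exactly 3-fold (the extremes are pinned) so normalization
is never a no-op. An optional shared `gene_factor` vector lets an
external cohort reuse the discovery cohort's gene-level abundance —
required for any correlation-based projection to be meaningful, since
real cohorts share gene biology. Not emulated: gene–gene correlation
within modules beyond the common group effect, batch structure, or
length/GC biases; recovery results therefore speak to statistical
power under clean modular structure, not to robustness against
confounded real data.

**Survival.** Exponential event times with hazard
`baseline × exp(log_hr × 1[IM-L])` (defaults: 0.01/month RFS,
half that for OS, log HR = ln 10), censored by an independent uniform
draw whose horizon is solved numerically so the expected censoring
fraction matches `censor_rate` (0.35). Clinical covariates (stage,
gender, smoking) follow the cohort's published distribution and are
independent of subtype — adequate for hazard-recovery tests, not for
confounding studies.

## Consensus filtering

Variant keys are normalized by trimming shared suffix then prefix
bases (never emptying an allele); with a reference sequence supplied,
indels are additionally left-aligned. Normalization is idempotent and
requires no downloads. Thresholds are strict inequalities exactly as
the filters define them: > 5% per strand, pan-cancer count > 3,
"two of three" means ≥ 2 PASS verdicts (an observed-but-filtered
record counts as observed, not passed). Strand VAFs come from a
designated primary caller (default the platform caller `ionreporter`),
falling back to the first caller reporting the locus; a zero-depth
strand reads as VAF 0 and fails the strand test — the conservative
convention. Missing annotations count as "no external evidence". The
TMB denominator is configurable and defaults to 50 Mb (exome scale).

## Clonal reconstruction

This stage is a deliberate desk-scale substitute for MCMC subclonal
phylogeny samplers, and its output is labelled as a substitute-method
call. The pieces the downstream analysis consumes — cluster count,
branched/linear class, trunk membership, purity — are recoverable
from a 1-D Gaussian mixture over CCFs (diagonal EM, k-means++
initialization, 10 restarts, BIC over k = 1..5, mutations sorted
canonically so input order cannot change the fit) plus a
deterministic tree builder. The builder takes clusters in descending
CCF order and attaches each to the **largest-CCF** node satisfying
child ≤ parent and the sibling sum rule (tolerance 0.05): clusters are
siblings as high as the pigeonhole principle allows and nest only when
forced (e.g. means {1.0, 0.6, 0.5} force 0.5 under 0.6 → linear,
while {1.0, 0.45, 0.4} remain siblings → branched). A
smallest-host preference was rejected because, processed in descending
order, every cluster can always nest under the deepest childless node,
so no tree could ever read branched. Ties break toward the lower
cluster index; an unplaceable cluster falls back to the trunk. The
trunk is exempt from the hard sum-rule assertion because the fallback
may overfill it on pathological inputs. Purity is 2 × mean trunk VAF
clamped to (0, 1]; when no purity is given, a provisional estimate
(2 × mean of the top VAF quartile) seeds the CCF transform. At the
validated operating point (ΔCCF ≥ 0.3, ≥ 50 mutations/cluster,
CCF sd 0.05), cluster count and branching are each recovered in
≥ 95% of 200 simulated tumors; closer subclones will merge, which is a
property of the data, not the estimator.

## Subtyping

**TMM.** Implemented from the definition: reference sample = column
whose 75th-percentile library-size-scaled count is nearest the mean
(quantiles of raw counts would be depth-confounded); M-values trimmed
30% per tail, A-values 5% per tail; precision-weighted (delta-method
variances) mean of M; factors rescaled to geometric mean 1; normalized
values are log2 CPM with effective library sizes. Factors agree with
edgeR's `calcNormFactors` to ~1e-5 on a planted-DE fixture, which the
suite re-checks through Rscript.

**Consensus NMF.** Features are the 1,500 most variable genes of the
log2-CPM matrix with each gene's minimum subtracted (per-gene baseline
removal; a global shift is a no-op on non-negative data and leaves a
constant offset that rank-2 factorizations spend on the mean rather
than the subtype split). Each rank 2..6 runs 30 random-restart NMF
fits (multiplicative updates, Frobenius objective, 200 iterations or
relative tolerance 1e-6); the W/H scale ambiguity is resolved by
normalizing W's columns before the per-sample argmax that defines the
per-run hard clustering. Co-clustering frequencies form the consensus
matrix; average-linkage hierarchical clustering of consensus
dissimilarity yields the cophenetic coefficient, consensus labels and
silhouettes. The selected rank is the smallest within 0.02 of the
maximum cophenetic coefficient; the subtype split itself is always the
two-cluster consensus, matching the study design of a binary
immune-high/low system, with higher-rank diagnostics reported.

**SAM.** d = (mean₂ − mean₁)/(s + s₀) with the pooled two-sample
standard error s and s₀ = median of s across genes (a documented
simplification of the percentile-optimization in the original
procedure). The null pools |d*| across genes over label permutations
(default 500); p-values use add-one smoothing. Pooling across genes
gives fine-grained p-values at small sample sizes and calibrates to
the nominal 5% level within Monte-Carlo error on null data.

**Scoring.** The per-sample gene-set score is the summed running
difference between in-set and out-set cumulative distributions down
the sample's expression ranking, both weighted by rank^0.25 and
normalized by gene count. Weighting both CDFs (rather than only the
in-set one) makes random sets score ≈ 0; the statistic is rank-based
and so invariant to monotone transforms of a sample's expression. The
purity proxy is −(immune + stromal) min-max rescaled to [0, 1] — only
the ordering claim (immune-high ⇒ lower purity) is meaningful, not
the scale. Cell-type scores are marker-gene means of normalized
expression.

**Labelling and projection.** The cluster with the higher mean immune
score is Immune-High; exactly equal means raise an error demanding a
manual override. Projection is nearest-centroid over the
SAM-significant gene panel: Spearman correlation after subtracting the
per-gene centroid mean (training-anchored centering, so the centroids
become contrasting profiles — without it, immune-low samples correlate
almost equally with both centroids because the centroids share the
gene-abundance ranking), an assignment margin of 0.1, and an
uncentered-similarity gate of 0.2 that keeps out-of-distribution
samples unassigned (mirror-image centered centroids would otherwise
hand noise samples margins that straddle the threshold). Gene matching
is exact-string; no alias resolution.

## Survival

Estimation is delegated to lifelines: product-limit curves, the
log-rank chi-squared with hypergeometric variance, and Cox partial
likelihood with Efron tie handling (the convention of R's `survival`,
which the suite cross-checks through Rscript). Confidence intervals
are 95% Wald on the log hazard. Monotone likelihood (complete
separation) returns a non-converged result with a diagnostic; fits
with absurd standard errors (SE > 10) are flagged as near-separation
and their hazard ratios are not propagated as point estimates — at
n = 17 with a strong subtype effect this is the expected regime, and
the log-rank test carries the inference. Stage enters adjustment
ordinally (IA = 1 … IV = 7).

## Problem sizes

Validation sizes were chosen to give tight Monte-Carlo error at desk
scale: 200 tumors for subclone/branching recovery, 200 planted drivers
for trunk-rate recovery, 50 replicate 17-sample cohorts for subtype
recovery, 1,000 null genes × 500 permutations for SAM calibration,
100 replicates at 500 subjects/arm for Cox hazard-ratio recovery, and
exhaustive enumeration of 2×2 tables with cells ≤ 5 for the Fisher
oracle. The acceptance script analyses one full 21-tumor cohort at the
default study conditions.

## Known limitations

- Copy-number variation is absent throughout: CCFs assume diploid
  heterozygous sites, and purity inherits that assumption.
- The clonal tree is a point estimate under a fixed ambiguity
  convention; posterior uncertainty over topologies is out of scope.
- Fisher-exact differential expression on pooled group counts is
  anti-conservative under overdispersion (library-scale counts make
  tiny proportion shifts "significant"); it is reported as defined
  above, with SAM as the calibrated alternative alongside it.
- The manual review step that distilled a final mutation list in the
  original workflow (IGV curation) has no computational analogue; the
  pipeline emits the F2 candidate set with flags instead.
- Projection assumes the external cohort shares gene-level abundance
  structure with discovery; cross-platform effects are not modelled.
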