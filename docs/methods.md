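# Methods

This note documents the statistical procedures, the generative model behind
the synthetic data, the defaults and why they were chosen, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Analysis procedures

**Gene filters.** Two filters run on *raw* counts, in either order (their
removal sets are independent): (1) genes with mean count across all seeds
strictly below 1 are removed; (2) within each condition separately, the
Pearson correlation between a gene's raw counts and the per-seed intergenic
read totals is computed, and a gene is removed if r is strictly above 0.3
in *any* condition. Intergenic reads act as a per-seed contamination
covariate: genes tracking them are suspected of reflecting background
rather than expression. Zero-variance genes within a condition cannot
correlate and are assigned r = 0 there (logged). All boundary comparisons
are strict, exactly as the thresholds are written ("<1", ">0.3", ">0.5").
Computing the correlation on raw rather than normalized counts is a
deliberate choice: contamination scales with the raw intergenic read count,
not with depth-normalized expression.

**Normalization.** x̃ᵢⱼ = ln(1 + xᵢⱼ / Σⱼxᵢⱼ · S), S = 10,000 by default
(counts-per-10k, log1p). It is deterministic, analytic, and invariant to
library size — doubling every count of a seed leaves its profile
unchanged. Variance-stabilizing regression normalizations used by
single-cell toolkits are intentionally not reproduced; the downstream
correlation threshold (0.5) is validated on synthetic data under this
normalization rather than assumed transferable.

**Differential expression.** Per gene, a two-sided Wilcoxon rank-sum test
on normalized values. The exact null distribution is used when the combined
sample size is ≤ 12 and there are no ties; otherwise the normal
approximation with midranks, tie-corrected variance, and continuity
correction (this is also the vectorized path for genome-wide comparisons).
The fold change is log₂((mean_A + c)/(mean_B + c)) of *de-logged*
(expm1) normalized means with pseudocount c = 0.1 — the pseudocount keeps
low-expression genes from producing unbounded fold changes and is
configurable. BH correction runs over exactly the genes tested in that
comparison (no pooling across comparisons). A call requires both adjusted
p < 0.05 and |log₂FC| > log₂(1.2) ≈ 0.263.

**Modules and signatures.** Gene–gene Pearson correlation across seeds
(zero-variance genes must be excluded first; they are an error, not a
silent NaN). Modules are connected components of the graph with edges where
r > 0.5 (strict), keeping components of ≥ 10 genes, labelled "cluster 1",
"cluster 2", … by descending size with ties broken by the lexicographically
smallest gene id. Connected components were chosen over fancier graph
clustering because the procedure is deterministic, has no tuning
parameters beyond the already-specified edge threshold, and is validated
end-to-end by planted-truth recovery tests. A module score is the plain
per-seed mean of normalized expression over the module's genes (an optional
control-gene background correction is deliberately not applied by
default).

**Module orientation.** The germination-competence index needs to know
which module is germination-associated. Seeds recovering from dormancy
induction advance toward germination, so the module whose mean score
increases more from the first condition (induction) to the last (recovery)
is taken as the germination module; with fewer than two conditions the
label order is kept and a warning is emitted. On planted data this rule
recovers the true orientation in every tested run.

**Size signature.** From a large-vs-small DE table: score =
mean(normalized expression of genes up in large) − mean(genes up in
small), so higher = transcriptionally more large-seed-like. This sign
convention follows the reading of the signature as "similarity to large
seeds".

**Isoform usage.** 3′-end read positions are counted strand-aware in
half-open [start, end) windows — BED-native, and shared boundaries are
never double-counted. The usage statistic is r = proximal/distal; ratios
with a zero denominator are undefined (NaN, not infinity), excluded from
tests and reported with a count. p̂ = r/(1+r) recovers the proximal-usage
fraction exactly when the windows capture all reads. Small-vs-large
comparisons pair per-replicate ratios (paired t-test) when both classes
cover the same replicates, else fall back to the rank-sum test.

**Phenotype statistics.** Seed area = mean of two pixel-area measurements ×
(mm/px)². The germinated-vs-dormant size comparison tests *pooled* seeds
from all replicates while reporting per-replicate class means — note the
pseudo-replication caveat: the pooled test treats seeds, not replicates, as
the unit of inference. Non-germinated seeds form their own class in the
day-of-germination analysis. Extreme selection takes the floor(fraction·n)
smallest and largest seeds with ties broken by seed id; for fraction ≤ 0.5
the two sets are disjoint by construction.

## The synthetic experiment

The generator emulates the structure of a two-condition secondary-dormancy
single-seed experiment: per condition 96 seeds in 3 pools of 32, with a
dormancy-induction time point ("3d") and a recovery time point ("7d24h").

Per seed i and gene j:

- latent germination axis gᵢ ~ Normal(μ_cond, 1); condition means (0, 0.5);
  in the recovery condition a fraction π = 0.25 of seeds (the "comet
  tail") is shifted by +2.0 along the axis;
- size covariate zᵢ with corr(z, g) = ρ (default 0.6), implemented as a
  bivariate-normal draw. Mirroring the sequencing design, the seeds of each
  condition are *pre-selected* from the two tails of the size distribution
  (default: outer 10% per side; `selection_quantile=0.5` recovers an
  unselected pool with a median-split labelling). `class_label` records
  small/large;
- counts xᵢⱼ ~ Poisson(Lᵢ · βⱼ · exp(loadⱼ · gᵢ)), with library size
  Lᵢ = 10,000 genic reads (a lognormal-spread knob exists, off by
  default — see Limitations), baselines βⱼ lognormal (σ = 1) normalized to
  sum 1, and loadings +λ for the 50-gene germination module, −λ for the
  50-gene dormancy module (λ = 0.8), 0 otherwise. A dispersion knob
  switches to negative binomial; Poisson is the default because shallow
  UMI counts are well approximated by it and it keeps the oracles
  analytic;
- planted gene sets (modules, contamination targets) are drawn among genes
  with expected count ≥ 2.5, since their real counterparts (translation
  and dormancy regulons) are expressed well above the QC floor;
- intergenic reads Iᵢ ~ Poisson(f·Lᵢ) with f = 0.05 (a "relatively low"
  intergenic fraction of ~5%); contaminated genes receive additional
  Poisson(κ·Iᵢ) counts (κ = 0 by default; contamination experiments use
  κ = 2 with 50 target genes);
- the two-isoform locus draws Binomial(N, p_prox) of N = 1,000 3′-end
  reads into the proximal window (default p_prox = 0.7), the rest into the
  distal window, uniformly within each window (synthetic coordinates on
  chr5);
- phenotypes: sizes sᵢ ~ Normal(0.11, 0.015) mm² truncated at zero (a
  plausible scale for Arabidopsis dry seeds), germination probability
  logistic(a + b·zᵢ) on the standardized size with a = 0 (≈50% germination,
  mid-range of secondary-dormancy inhibition) and b = 2; day of
  germination is 1 + a geometric draw with success probability
  logistic(0.4 + 0.5·zᵢ), capped at the day-7 scoring horizon, so larger
  seeds germinate earlier. Capping (rather than re-labelling late
  germinators as dormant) keeps the b = 0 null exact: with no planted
  link, size and germination are independent in law.

Same seed ⇒ bit-identical outputs. The pipeline fans one seed out to
per-stage child seeds via `numpy.random.SeedSequence([seed, stage])`, so a
stage rerun alone reproduces its stream.

## Numerical choices

- PCA: centered SVD; components are oriented so the largest-magnitude gene
  loading is positive (deterministic sign).
- Per-gene z-scaling uses the sample (ddof = 1) standard deviation;
  zero-variance genes map to all-zeros instead of NaN.
- Identical samples in the rank-sum test yield p = 1; zero-variance paired
  differences are an error for the paired t-test (t undefined) and p = 1
  in the isoform-ratio comparison (no evidence either way).
- The isoform-calibration check uses the central *exact* binomial
  acceptance region of the planted p_prox (0.025/0.975 quantiles of
  Bin(N, p)) rather than the normal-approximation interval; its exact
  coverage at N = 1,000, p = 0.7 is 0.9546.
- MTX output is written in canonical (seed, gene) order; dense-TSV files
  carry reserved `__intergenic__`/`__condition__`/`__class__` rows so both
  dialects round-trip the full object.

## Problem sizes

Validation runs use 2,000 genes and 96 seeds per condition (the full
pipeline on 192 seeds), 10 generator replicates for recovery and error-rate
checks, 50 replicates for the signature-correlation headline, 200 loci for
isoform calibration, and 20 replicates of 500-seed (plus 4 × 1,000-seed
extreme-selection) phenotype experiments. These sizes give sub-percent
Monte-Carlo error on the reported fractions while keeping a full validation
run around ten seconds.

## What passing tests do and do not show

The generator plants clean, well-separated structure: Poisson noise, two
disjoint equal-sized modules, a single latent axis, exactly two seed
classes. Real single-seed data add overdispersion, batch/pool effects,
ambient contamination that is not a simple Poisson leak, partially
overlapping regulons, and modules of very different sizes. Passing the
recovery tests therefore demonstrates correctness of the implementations
under the stated model, not that the thresholds (0.3, 0.5, log₂1.2) are
optimal for any particular real dataset.

Known limitations:

- With both conditions pooled (and the comet tail present), abundant
  background genes acquire mutual correlation through the compositional
  coupling of counts-per-10k normalization and can attach to the
  dormancy-module component, inflating it by a few dozen genes; module
  scores and the signature correlation are robust to this, but membership
  Jaccard against planted truth degrades relative to the single-condition
  case.
- Shared library-size variation (the `library_size_sigma` knob) couples
  every gene to the intergenic totals and makes the intergenic filter
  over-fire by design; it is off by default so that the filter's null
  behavior matches the null distribution of Pearson r.
- The pooled germinated-vs-dormant test ignores replicate structure
  (pseudo-replication), as noted above.
- Seed-pool size distributions are symmetric normals; real pools show
  replicate-specific skewness. A skew knob would be a straightforward
  extension.
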