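# Methods

## Setting

`omicsets` analyzes studies in which D genomic data types ("platforms",
e.g. two expression arrays E1/E2 and two copy-number summaries C1/C2) are
measured on the same samples and summarized per gene, together with a
phenotype Y — a binary class label or a right-censored survival time. The
goal is to rank annotated gene sets by their association with the
phenotype while using all platforms jointly, in a two-stage framework:

* **Stage I** — a per-gene association score.
* **Stage II** — a set-level test on the stage-I scores.

## Stage I: deviance-difference scores

For a binary phenotype and gene g, platform d, the single-platform score is
the likelihood-ratio statistic of the one-predictor logistic regression

    s_g^d = D(null) − D(y ~ x_g^d),

where D is the deviance (−2 log-likelihood). The integrative score uses one
multivariate logistic regression containing, as predictors, the gene's
measurements on *every* platform in its availability set:

    logit E(Y_i | x) = β_0 + Σ_d x_gi^d β_gd,     s_g = D(null) − D(fit).

Under the null, s_g^d is asymptotically χ²(1) and s_g is χ²(k) for a gene
measured on k platforms. Both are non-negative and equal 0 exactly for a
constant predictor. Because models with more predictors always fit at least
as well, s_g ≥ s_g^d for every available d (nestedness) — and s_g grows
with the number of platforms even for pure noise, which is why the choice
of gene universe matters in stage II (below).

For survival phenotypes the logistic deviance is replaced by the Cox
partial-likelihood ratio, 2·(log PL(fit) − log PL(null)), with the Breslow
approximation for tied event times.

Numerical choices:

* Fits use Newton/IRLS batched across genes (one `(genes, samples,
  predictors)` stack per availability pattern), with a warm start at the
  intercept-only optimum, step-halving on deviance increase, and a
  deviance-change stopping rule of 1e-10. Each converged fit matches a
  direct likelihood maximization to well below 1e-6.
* Predictors are standardized per gene before fitting. Deviance differences
  are invariant to affine predictor transforms, so this only improves
  conditioning.
* A 1e-10 Tikhonov jitter on the Newton step keeps flat directions
  (constant or collinear predictors) solvable without moving the optimum.
  An optional ridge penalty exists but is off by default — the default path
  is the plain maximum-likelihood fit.
* Complete separation is detected when all fitted probabilities pin to 0 or
  1 within 1e-8; the score is then capped at the null deviance and the gene
  is flagged. Non-convergent fits are flagged and keep their best iterate.
  Flags never abort a score table.

## Gene universes

* **intersection** — genes measured on all D platforms. Required by the
  competitive test: deviance scores grow mechanically with the number of
  predictors, so genes measured on fewer platforms would be unfairly ranked
  against genes measured everywhere.
* **union** — genes measured on at least one platform. Allowed for the
  self-contained test, because each gene is compared against its own
  permutation null, which carries the same number of platforms by
  construction.

## Stage II: set tests

**Competitive** (one-sided Mann-Whitney): are the scores of genes in set s
larger than the scores of the remaining annotated genes? Exact enumeration
when min(n_in, n_out) ≤ 8 with no ties; otherwise the normal approximation
with tie correction (no continuity correction by default; switchable). All
sets of a collection share one ranking, computed once.

**Self-contained** (permutation-averaged signed rank): the study is
re-scored under B = 500 independent phenotype-label shuffles (computed once
and shared by all sets). For each permutation b, the one-sample Wilcoxon
signed-rank statistic W_b of the paired differences (observed minus
permuted score over the set's genes) is computed; the average W̄ is
referred to the upper tail of the signed-rank normal approximation with
mean n(n+1)/4 and variance n(n+1)(2n+1)/24. Zero differences take half
weight (mid-rank tie rule), so an all-tied permutation lands exactly on the
null mean. Averaging the raw (unstandardized) W is this package's
documented choice. Note that averaging over permutations shrinks the
spread of W̄ slightly below the nominal single-statistic null, making the
test mildly conservative in the far tails; empirically the P-values remain
statistically indistinguishable from uniform at benchmark scale.

Both tests are rank-based, hence invariant to strictly monotone transforms
of the score scale, and one-sided throughout: scores are non-negative
association strengths and enrichment means larger scores.

**Meta-analysis**: when each platform is tested separately, per-set
P-values are combined by geometric mean (AvgP — evidence from several
platforms required) or minimum (MinP — strong evidence from any single
platform suffices; reported uncorrected since its use is ranking, with a
Bonferroni-style variant behind a flag). Raw P-values are reported;
Benjamini-Hochberg adjustment is available but off by default.

## Spike-in benchmark

The benchmark asks each method to recover gene sets whose association with
the phenotype was planted by construction.

**Backbone.** The null study has no true associations. Users with real
matrices get the exact construction via label permutation
(`permute_labels_backbone`), which preserves all gene-gene and
cross-platform correlations. The self-contained synthetic backbone
(`generate_backbone`) draws, by default, four independent standard-normal
platforms of 10,000 genes on 99 samples with a random 49/50 class split.
Two optional correlation structures emulate real multi-platform data:

* `rho_pair` — same-gene correlation between platforms of the same
  modality (E1/E2, C1/C2), via a shared latent component;
* `cn_autocorr_length` — AR(1) spatial autocorrelation along the genome
  ordering for copy-number-like platforms (correlation exp(−lag/length)),
  emulating amplifications/deletions spanning many genes.

**Collections.** `synthetic_collection` draws disjoint sets with sizes
log-uniform on [10, 100] (mimicking the size spread of curated canonical-
pathway collections) and assigns genes uniformly at random, so within-set
correlation equals between-set correlation by construction.
`band_collection` partitions the ordered universe into contiguous blocks,
emulating chromosome-band positional sets.

**Spike-in.** Ten sets are chosen at random. For each chosen set k and
*independently for each platform*, the number of altered genes is drawn
Binomial(n_k, γ) — γ is the expected altered fraction — and the shift Δ_k is
added to the class-1 samples of the altered genes. Δ_k solves

    power(two-sample t, Δ_k / sd_k, n1=49, n2=50, α=0.05 two-sided) = β

by monotone root-finding on the noncentral-t power function, where sd_k is
the average gene standard deviation in set k and β is the signal strength.
The grid β ∈ {0.166, 0.5, 0.84} corresponds to shifts of 1, 2 and 3
standard errors. A spiked set whose binomial draws come up empty on every
platform stays labeled true positive (no re-draw), conservatively
deflating measured power. All other matrix entries are bit-identical to
the backbone.

**Evaluation.** A set is a true positive if it shares ≥ 50% of its genes
with the union of the spiked sets' genes (for disjoint collections:
exactly the spiked sets). Methods are compared by true positives among the
top-k sets (k = 10; ties in P broken by set id, deterministically), by the
ROC/AUC of spiked-vs-non-spiked classification by P-value (trapezoid area
with tied P grouped, identical to the rank-statistic AUC; curves averaged
vertically on a 101-point specificity grid), and by exclusive-discovery
fractions: EF(i) is the fraction of platform i's true discoveries found by
no other platform, EF*(l) the fraction of an integration method's true
discoveries found by no single platform at all. Repetitions with no true
discoveries for the method are skipped in EF averages and counted.

Every scenario repetition draws a fresh backbone, collection and spike-in
from a spawned sub-seed of the master seed, so runs are exactly
reproducible and repetitions are independent.

## Default benchmark scale

The default scenario uses 10,000 genes per platform, 200 disjoint sets and
100 repetitions per grid point. The universe size is chosen so that a
200-set collection with sizes log-uniform on [10, 100] (expected total
≈ 7,800 genes) always fits with a comfortable margin of unannotated genes;
it also matches the scale of a typical all-platform intersection universe
in multi-platform cancer studies. 100 repetitions put the Monte-Carlo
standard error of a mean AUC near 0.005–0.01.

## What the synthetic backbone does and does not emulate

Passing benchmarks on the default backbone show that the pipeline is
correctly calibrated (null scores have χ² means, set-test P-values are
uniform under the null) and that integration gains power when the signal
is spread thinly across platforms (small γ). Two features of real
multi-platform data are *not* in the defaults:

* **Cross-platform same-gene correlation.** Real platform pairs measuring
  the same quantity are strongly correlated. A joint logistic model
  exploits this: a shift on one platform of a pair correlated at ρ has its
  noncentrality inflated by 1/(1−ρ²) given the other platform. Raising
  `rho_pair` therefore raises the integrative AUC substantially at weak
  signal while single-platform and meta-analytic AUCs barely move:
  independent platforms *understate* the integrative method's advantage
  relative to what correlated real data show.
* **Gene-gene correlation within a platform.** Co-expression and CN
  autocorrelation inflate the variance of competitive set statistics on
  real data; the independent default leaves the competitive test slightly
  optimistic about between-set variability. The `cn_autocorr_length` knob
  reproduces the qualitative CN failure mode (false positives clustering
  along the genome for band collections) but no attempt is made to match
  real copy-number AUCs quantitatively.

## Other design choices

* Survival dichotomization (extreme discordant phenotype design) labels
  samples strictly below the lower survival quantile as short-term (1) and
  strictly above the upper quantile as long-term (0); ties at a threshold
  are excluded. Quantiles use linear interpolation.
* A gene with any missing value on a platform is treated as unmeasured on
  that platform. Gene identifiers match as exact, case-sensitive strings;
  no symbol aliasing.
* Degenerate inputs fail loudly: one-class phenotypes, empty sample
  intersections, survival with fewer than two events, β ≤ α in the power
  calibration.

## Known limitations

* The integrative model requires all platforms on the same samples;
  studies measuring different samples per platform can only use the
  meta-analytic combinations.
* Each gene is assumed summarized once per platform; multiple probes per
  gene must be pre-summarized.
* Cox scoring loops per gene (no batched path); it is intended for
  moderate gene counts, not the simulation benchmark.
* MinP is reported uncorrected by default and is anti-conservative as a
  significance level; use the Bonferroni flag when calibrated P-values are
  needed.
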