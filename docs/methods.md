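# Methods

## Scores

The cell cycle score (CCS) of a sample is the unweighted sum of its log2
expression over a cell-cycle gene signature. Summation (rather than a mean
or z-score) keeps the score in interpretable log-expression units and
matches how such signatures are applied to co-normalised compendia; it is
only meaningful when tumour and normal samples have been normalised
together upstream, which the loaders assume and never re-do. Signature
genes absent from the matrix are counted and dropped — never imputed — and
scoring aborts when more than 20% of the signature is missing (ceiling
configurable), since a heavily truncated signature silently changes the
score's scale.

Gene *modules* (hormone receptor programmes, a proliferation metagene) are
summarised differently: the mean of per-gene z-scores across samples. The
divergence is deliberate — modules of unequal size must be comparable side
by side, which raw sums are not. Zero-variance module genes are excluded
with a warning.

## Baseline correction

A tumour's baseline-corrected score is

    BC-CCS(t) = [ CCS(t) − median CCS(GTEx normals of tissue(t)) ] × purity(t),

followed by min-max rescaling to [0, 1]. Decisions worth recording:

- **GTEx normals only** anchor the baseline. TCGA adjacent-normal tissue is
  retained for plotting but excluded from the median: adjacent-normals are
  known to carry field effects and tumour contamination.
- **Median, even-count convention**: mean of the two central values.
- **Order of operations is fixed**: subtract baseline, multiply by purity,
  then rescale. Rescaling before the purity product would let the purity
  multiplication push values outside [0, 1] and change ranks.
- **Missing purity**: tumours without a purity value are dropped with a
  logged count by default; an alternative policy imputes the cancer-type
  mean. Dropping is the default because imputation couples a tumour's
  score to its cohort composition.
- Purity multiplication is monotone for positive corrected scores and
  anti-monotone for negative ones; both behaviours are intended (a
  low-purity sample's apparent deviation from baseline, in either
  direction, is discounted).

Quadrant classification takes per-tissue medians of normal and tumour CCS,
min-max rescales each axis across tissues, and compares each axis to a
threshold (default 0.5, configurable). Ties at the threshold resolve HIGH.
Because each axis is rescaled, the call is invariant to any common affine
transform of the raw scores — the threshold is a statement about relative
position, not absolute units.

## Cohort filtering

The exclusion cascade is label-driven and order-fixed (non-compendium →
no mRNA → no matched site → small groups, then testis, then embedding
outliers) because stage-wise counts are only reproducible when the order
is pinned. The small-group rule removes normal-tissue groups and
cancer-type groups with fewer than `min_n` samples (default 10)
independently, then re-enforces site matching in both directions; one pass
suffices because matching removals delete whole tissue groups and cannot
create new small groups. Stage counts are reconciled on every run
(initial n − Σ removed = final n) and the cascade is idempotent.

Testis removal is label-driven, not geometry-driven: the embedding is used
to *justify* the removal, but the rule that executes it is "tissue ==
testis", so it is reproducible without manual inspection.

## Embedding QC and outlier flagging

"Most variable genes" means highest per-gene variance (ddof = 1), ties
broken lexicographically for determinism. PCA centres per gene and fixes
component signs by making each component's largest-magnitude loading
positive. UMAP runs with library defaults and a fixed seed; its
coordinates are reproducible per platform only.

The outlier rule replaces manual circling of aberrant samples on a PCA
plot: robust squared Mahalanobis distance in the first two components
(minimum covariance determinant location/scatter) against the
chi-square(2) quantile at 1 − α, default α = 0.001. Robust distances run
liberal in finite samples, so they are rescaled to put the sample median
at the chi-square(2) median before thresholding — a standard consistency
calibration. The rule assumes one elliptical bulk; on a strongly clustered
pan-tissue embedding it flags entire tissues, so the pipeline only
auto-removes flags when they cover at most `max_outlier_frac` (default 1%)
of the cohort and otherwise warns and keeps everything. Genuinely aberrant
samples are rare; whole-cluster removals need a human decision.

## Genomic comparisons

Displayed frequencies are macro-averaged: the mean over cancer types of
the within-type frequency, ×100. This removes the influence of unequal
cancer-type sample sizes and is invariant to duplicating all samples of
any one type. The Fisher exact test, in contrast, runs on pooled per-group
counts — a single two-sided p per feature. The direction filter
("enriched in group 2") is applied post hoc on the macro-averaged
frequencies, keeping the test itself two-sided.

The two-sided Fisher p sums conditional hypergeometric probabilities of
all tables no more probable than the observed one (relative tie tolerance
1 + 1e-7, the same rule scipy applies). It is evaluated vectorised over
the whole support via log-gamma, which keeps exhaustive verification
sweeps and many-replicate power simulations fast; the unit suite checks it
against both scipy.stats.fisher_exact and an exact integer-arithmetic
enumeration. The reported odds ratio is the sample cross-product ratio.

A Cochran–Mantel–Haenszel stratified mode exists but requires an explicit
per-sample stratum label that cuts across both groups (e.g. batch).
Stratifying by cancer type is impossible here: the comparison groups are
*sets of* cancer types, so every cancer-type stratum would contain members
of one group only and the test is undefined.

Amplifications (+1) and deletions (−1) are tested separately per
chromosome arm, each direction with its own BH correction, over the 39
standard autosomal arms (acrocentric p-arms excluded).

## Differential expression

Per-gene OLS uses cell-means coding — one indicator per cancer type plus
the ESR1 log-expression covariate — with the group effect expressed as the
contrast mean(group-2 type means) − mean(group-1 type means). An
intercept + group-indicator parameterisation is rank-deficient in this
design because cancer types are nested within groups; the cell-means
contrast is the standard linear-model idiom for nested group comparisons
and weighs each cancer type equally, consistent with the macro-averaged
frequencies above. ESR1 itself is excluded from the tested genes when used
as a covariate.

Residual variances are shrunk by empirical Bayes: with per-gene sample
variances s²_g on d residual df and a scaled-inverse-chi-square prior
(d0, s0²), the posterior variance is s̃²_g = (d0 s0² + d s²_g)/(d0 + d)
and the moderated t = contrast / (se · s̃_g) has d0 + d df. The prior is
estimated by moment matching on log s²_g (digamma/trigamma expressions;
trigamma inverted by Newton iteration); an empirical spread no larger than
the sampling noise yields d0 = ∞ (fully pooled variances). The
implementation is validated by its two analytic limits — d0 = 0 recovers
the ordinary OLS t exactly, d0 = ∞ pools every gene at s0² — and by null
calibration (uniform p on 2,000 simulated null genes).

Significance is |log2FC| strictly greater than 2 *and* BH-FDR below 5%;
the fold-change boundary is strict (a gene at exactly 2.0 is excluded).

## Preranked GSEA

The ranking statistic defaults to sign(log2FC) × (−log10 p), combining
effect direction with evidence; t-statistic and plain log2FC orderings are
available. Ties break by |log2FC| then gene id; p = 0 is replaced by the
smallest positive float with a warning.

The enrichment score is the signed maximum deviation of the weighted
running sum (hit increment |statistic|, exponent 1, normalised by the
in-set total; miss decrement 1/(N − Nh)). The null distribution places the
set's Nh genes uniformly at random in the ranking (gene-label
permutation), vectorised across permutations. p is empirical within the
matching-sign null, NES divides ES by the mean |null ES| of matching sign,
and set-level q-values are BH across sets (simpler and better defined than
the classic two-tailed permutation FDR, which remains a possible
extension). Sets with fewer than 5 genes in the ranking are skipped with a
warning. Default thresholds: 1,000 permutations, FDR < 10%.

## Synthetic cohorts

The generator emulates what the pipeline assumes of a co-normalised
normal + tumour compendium, directly in log space (no count model — the
pipeline never consumes counts):

- signature genes: Normal(baseline_t, σ) in normals of tissue t,
  Normal(baseline_t + uplift_t, σ) in tumours; a disjoint "proliferation
  metagene" set shares the same means, giving the strong CCS–metagene
  correlation seen in real cohorts;
- background genes: Normal(0, σ), with a planted subset shifted by a true
  log2FC in group-2 tumours and hormone-module genes shifted by a
  configurable amount;
- purity ~ Beta(5, 2) (mean ≈ 0.71, matching typical consensus purity
  distributions); mutations Bernoulli with per-gene base rates and
  group-2 odds multipliers; arm calls Bernoulli per (arm, group) rate with
  a fixed gain/loss direction per arm (enriched deletions emitted as −1,
  amplifications as +1).

Default study conditions: 8 tissues spanning the observed regimes
(high-baseline/low-uplift head-and-neck, low-baseline/high-uplift
gynaecological tissues, intermediates), 30 normals and 60 tumours per
tissue (100 tumours per tissue in the recovery runs), σ = 1, driver
rates in the familiar pan-cancer order (TP53 0.45 > PIK3CA 0.25 >
PTEN 0.15 > FBXW7 0.08), and 16q/8p deletions plus 3q/1q gains enriched at
0.6 vs 0.2 in the gynaecological group. One global seed feeds fixed
per-component sub-streams (expression, purity, mutations, arms), so adding
a component never perturbs earlier draws and identical seeds give
bitwise-identical cohorts.

A deterministic CONSORT fixture manifest reproduces the published
cohort-selection bookkeeping (19,131 samples; 734/92/802/4,043 primary
exclusions; 319 testis; 24 embedding outliers; 13,117 retained as
4,979 normals + 8,138 tumours) with plausible tissue/cancer-type labels.

What the generator does **not** model — and therefore what passing
recovery tests do not show about real data: RNA-seq count noise,
library-size and dispersion effects, batch structure, correlated genes
within a sample beyond the block means, mixed cell populations within
normals, and per-sample baseline heterogeneity. The generator verifies the
*pipeline's arithmetic and inference*, not the biology.

## Problem sizes and numerics

Recovery runs use 8 tissues × 100 tumours (uplift ranks), 250 samples per
group × 200 replicates (arm power), and 50 seeded cohorts of 100 tumours
per group (DE recovery) — sizes chosen so each statistic's sampling error
is small relative to the margins being tested. Exhaustive Fisher
verification covers all 313,600 tables with n ≤ 50. Degenerate inputs are
hard errors rather than silent NaNs: constant score ranges, single-tissue
quadrant requests, rank-deficient designs (with the aliased columns
named), zero signature overlap, out-of-range purity or arm codes.

## Known limitations

- Baselines are per-tissue medians; per-sample matched-normal correction
  and stratification by hormonal status are out of scope.
- The BC-CCS rescaling order (purity before min-max) is a convention;
  the alternative order is a one-line config change but alters the scaled
  values, not the ranks, of purity-adjusted scores.
- UMAP coordinates are reproducible only within a platform/library
  version.
- GSEA set-level FDR via BH over permutation p-values is slightly
  conservative for small permutation counts.
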