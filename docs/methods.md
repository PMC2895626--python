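# Methods

## Problem and approach

Gene-level prognostic signatures from expression cohorts are notoriously
unstable: resampling the same cohort, or moving to another cohort, produces
largely different top-gene lists of similar predictive ability.  `setsig`
implements the set-statistic approach to this problem: predefined gene sets
(MSigDB-style collections) are reduced, one set at a time, to a single value
per sample — an unsupervised *set statistic* — and those set-level features
replace individual genes as inputs to a simple, heavily regularised linear
classifier.  The package then quantifies what is gained: equal
discrimination with markedly more stable feature rankings within and across
cohorts.

## Set statistics

Given the expression submatrix of set *j* (s genes × N samples), the six
statistics are:

- **centroid** — per-sample mean over the member genes.  For uncorrelated
  equal-variance genes the feature's noise variance drops as 1/s (the square
  of the standard error of the mean); correlation between members reduces the
  gain.
- **median** — per-sample median; the centroid's outlier-robust sibling.
- **medoid** — the single member gene whose full across-sample profile is
  closest (Euclidean) to the centroid profile; one real gene represents the
  set.  Ties break to the lowest row index.  Inside a validation split the
  distance uses training columns only, so test samples never influence the
  choice.
- **t-statistic** — on gene-standardized data (each gene mean 0, unit sample
  variance, divisor n−1), centroid ÷ (within-sample SD of members / √s).
  Standardization prevents small-variance genes from producing spurious
  statistics.  Sets with fewer than `min_tstat_size` (default 30) genes are
  excluded; the within-sample SD is guarded below by 1e-8.
- **rank-sum (U) signed log p** — within each sample all p genes are ranked
  (ascending, average ranks on ties); U = (sum of member ranks) − s(s+1)/2.
  Under the null U ≈ Normal(μ = s·s¬/2, σ² = s·s¬(s+s¬+1)/12).  The feature
  is sign(z)·(−ln p_two-sided) with p floored at the smallest positive
  double.  The sign is a package decision: it preserves the direction of the
  expression change, which a linear classifier needs; base e, no continuity
  correction.
- **PC1** — the projection onto the first right-singular direction of the
  column-centred, unit-variance-scaled N×s matrix.  The SVD sign is
  arbitrary, so it is fixed by requiring non-negative correlation with the
  set centroid.  Zero-variance genes are dropped from the decomposition and
  logged.

`raw` passes the gene matrix through unchanged and is the individual-genes
baseline everywhere.

## Centroid classifier

c⁺ and c⁻ are the feature-wise means of the two classes; w = c⁺ − c⁻ and the
decision value for sample z is ŷ = ⟨z − (c⁺+c⁻)/2, w⟩, thresholded at 0.
The raw ŷ (not its sign) feeds the AUC, which lowers the AUC estimate's
variance.  AUC is the Mann–Whitney statistic with ties credited ½.  Each
weight depends only on its own feature, so recursive feature elimination is
a single sort by |w| — truncating to the top k and refitting reproduces the
same weights.  The classifier is equivalent to diagonal-covariance LDA with
uniform priors and needs no tuning.

## Validation and bagging

Internal validation: B = 25 random splits into 2/3 training and 1/3 testing
parts, stratified by class (the cohorts run ~1:4 events to non-events; an
unstratified split can lose a class from the training part).  Each split
fits one model; a sample's bagged prediction is the mean of its held-out
decision values over splits, and one pooled AUC per feature count is
computed from those (per-split held-out AUCs are also recorded for spread).
External validation: for each ordered pair of cohorts, a bagged classifier
(B subsamples of the training cohort) scores every sample of the test
cohort — D(D−1) ordered pairs, 20 for five cohorts.  Cross-cohort feature
spaces are aligned by feature-id intersection before statistics are
computed.  Per-pair subsampling seeds derive deterministically from the
master seed via `SeedSequence`, so reports reproduce bit-for-bit.

The variance of AUC values gets a two-sided chi-squared confidence interval,
((n−1)s²/χ²₁₋α/₂, (n−1)s²/χ²α/₂).

## Stability measures

- **Bootstrap rank intervals**: samples are resampled with replacement
  within each class (stratified, so no replicate is single-class; default
  5000 replications), the model refitted, features ranked by |w|; per
  feature the mean rank and the empirical 2.5%/97.5% percentiles
  (type-1/inverse-CDF quantiles, so intervals are bit-reproducible).
- **Weight concordance**: Spearman ρ between the weight vectors of
  single (non-bagged) models from different cohorts, all unordered pairs.
- **List overlap**: for each cutoff f, the number of features ranked in the
  top f of at least k of the D cohorts' lists; also the smallest f at which
  the first all-cohort-common feature appears.
- **Consensus rank**: features ordered by mean rank across cohorts, ties by
  name.

When genes are compared with sets, the comparison uses equal feature counts:
the gene list is the top |M| genes of a classifier trained on a *reference*
cohort, fixed across replications, so gene-side selection is not biased by
the cohort under study.

## Enrichment

Category enrichment along a ranked set list is the two-sample
Kolmogorov–Smirnov test on the rank positions of in-category versus
out-of-category sets.  The Brownian-bridge curve (running F_in − F_out,
zero at both ends) is computed in-package; its maximum absolute value is D.
The p-value is the asymptotic two-sample KS p (scipy), with a
label-permutation alternative (≤10⁴ permutations) for small categories.

Top-list overlap uses the hypergeometric upper tail P(X ≥ overlap),
summed in log space from log-pmf terms built on `gammaln` — tails far below
1e-40 (the regime the strongest co-expression sets reach against a 512-gene
top list in a 22,215-feature universe) remain accurate.  The universe size
is an explicit parameter defaulting to the number of matrix features.
Bonferroni-style correction for many sets is left to the caller.

## Subtyping

ER and HER2 module scores are signed means of gene-standardized expression
over user-supplied module gene lists (±1 direction per gene; genes absent
from the matrix are skipped and logged).  Module weighting schemes richer
than signs exist in the literature; sign-based scoring is this package's
documented stand-in.  The 2-D score cloud is clustered with a
three-component full-covariance Gaussian mixture fitted by EM: k-means-style
initialisation under the seed, 10 restarts keeping the best final
log-likelihood, convergence at log-likelihood improvement < 1e-8 or 500
iterations, covariance collapse regularised with 1e-6·I (flagged).  The
log-likelihood trace is exposed and non-decreasing up to round-off.
Components map to subtypes by their means: highest HER2-axis mean → HER2+;
of the remainder, higher ER-axis mean → ER+/HER2−.  Ties beyond 1e-8 raise
rather than guess.

## Synthetic data generator

The generator emulates the structure the method assumes, at desk scale:

- Each set has one latent factor per sample (standard normal); a member gene
  is √ρ·factor + √(1−ρ)·noise, targeting within-set correlation ρ.  Genes in
  several sets are driven by the first set that claimed them; genes outside
  all sets are pure noise.
- Informative sets shift their factor by δ in event samples.  Their factors
  additionally share one latent signal (`shared_signal_frac` = 0.8 of factor
  variance): outcome-linked sets in real cohorts overwhelmingly reflect a
  single biological program (proliferation, in breast-cancer prognosis), and
  without that sharing twenty independent shifted factors would stack into
  near-perfect separation instead of the AUC ≈ 0.7–0.8 such cohorts actually
  show.
- Every gene is multiplied by a log-normal scale (`gene_scale_sd` = 0.5)
  drawn independently per cohort: probesets differ widely in dynamic range
  and each cohort is normalised by its own pipeline.  Scaling a whole row
  leaves correlations and per-gene discrimination untouched but confounds
  raw centroid weights — the distortion the t-statistic's standardization
  removes.
- Per-cohort batch offsets (per-gene N(0, `batch_shift_sd`)), uniform
  missingness, and a 1:4 event:event-free class ratio complete the picture.

Defaults describe a five-cohort compendium at desk scale: p = 2000 genes,
120 samples per cohort, 200 sets of 10–50 genes, 20 informative, ρ = 0.6,
δ = 1.  What the generator does **not** model: probe-level artefacts,
heavy-tailed noise, censoring-time structure (labels are already
dichotomised), overlapping informative programs, and correlation between
noise sets.  Passing tests therefore show the machinery behaves as designed
under the stated structure, not that any particular real cohort will show
the same effect sizes.

## Benchmark protocol and known limitations

The stability benchmark (`setsig.experiments`) runs the full gene-vs-set
comparison on five generated cohorts per seed: bootstrap rank intervals
(R = 500) on cohort 0, equal-count gene list selected on the last cohort,
single-model weight concordance and overlap curves over all five, and
bagged external validation over all 20 ordered pairs.  AUC levels are
compared at the full feature count; AUC *variance* across the 20 pairs is
averaged over a feature-count grid ([8, 32, full]) because truncation by
|w| is where ranking instability acts.  Problem sizes were chosen so a
10-seed benchmark completes in well under a minute per seed on one CPU.

Directional results on this generator: narrower set-feature rank intervals,
higher set-feature weight concordance, earlier all-cohort-common set
features, and gene/set AUC agreement within 0.05 hold in essentially every
seed.  The fifth direction — lower across-pair AUC variance for the set
t-statistic than for genes — holds on aggregate but only in ~60–70% of
individual seeds: with 20 pairs the variance estimator's own sampling noise
(~30% relative) exceeds the true effect at this scale, so per-seed
comparisons of it are close to coin flips even when the underlying ordering
is correct.

## Numerical choices

- Probeset filtering: QC prefix "AFFX", variance ≤ 1e-8, missing fraction
  strictly > 0.15 removes the row; imputation by row median of non-missing
  values.
- Missing tokens "NA", "", "NaN"; configurable.
- Gene standardization uses the n−1 divisor throughout.
- AUC ties ½; rank ties average; |w| ranking ties keep original feature
  order (stable sort).
- Expression TSVs are written with %.17g and read with round-trip float
  parsing, so write-then-read is bit-exact.
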