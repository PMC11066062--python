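# Methods

`imnatac` reimplements, as a tested pipeline, the covariate-aware analysis chain
used for large bulk ATAC-seq cohorts of iPSC-derived motor neurons: consensus
peaks, count normalization, differential accessibility, variance partitioning,
X-inactivation background statistics, a clinical-slope predictor, and cis
peak–gene mapping. Because the real cohorts of this kind sit behind data-use
agreements, every analysis here is exercised on a synthetic cohort whose
planted structure is recorded, so each stage can be validated as a recovery
problem. This note documents the models, the generator, the numerical choices,
and what the synthetic validation does and does not establish.

## Count model and normalization

Fragment counts over a region catalog are modeled as negative binomial,
`K_ij ~ NB(mean = s_j q_ij, dispersion alpha_i)` with variance
`mu + alpha mu^2`. Sequencing depth enters only through the per-sample size
factor `s_j`, estimated by the geometric median-of-ratios rule over regions
with strictly positive counts in every sample. Per-region dispersions are
1-D maximum-likelihood estimates on `alpha in [1e-8, 10]` (log-scale bounded
search); the parametric trend `alpha(mu) = a1/mu + alpha0` is fit by
non-negative least squares with one-sided trimming (drop regions with
`alpha_hat > 2x` the current trend, iterate to a stable trimmed set, at most
10 rounds). We estimate per-region dispersions by plain MLE rather than an
empirical-Bayes shrinkage tower: the trend — which is what the
variance-stabilizing transform and the GLM consume — is preserved, and at the
cohort sizes used here (>= 150 samples) the MLE is already stable.

The variance-stabilizing transform (VST) integrates
`g(q) = ∫ dmu / sqrt(mu + alpha(mu) mu^2)`. With the substitution `u = sqrt(q)`
the integrand is smooth (`2 / sqrt(1 + a1 + alpha0 u^2)`), so a dense
cumulative trapezoid on 8192 points, interpolated monotonically (PCHIP), is
accurate well below 1e-6 (the closed form `(2/sqrt(alpha0)) asinh(...)` is used
as a test oracle, not in the code path). The transform is calibrated affinely
to read as log2 of normalized counts: when `alpha0` is materially positive the
slope is fixed at the exact asymptote `sqrt(alpha0)/ln 2` — so `g(q) - log2(q)`
converges to a constant for large counts — with the offset matched to `log2`
at the 75th percentile of normalized counts; in the near-Poisson limit
(`alpha0 < 1e-6`, square-root asymptote) a two-anchor secant through the
25th/75th percentiles is used instead. Any affine calibration leaves every
downstream correlation, selection, and fraction unchanged; only the printed
scale differs. The transform is blind to the design: it uses only the trend
and the marginal count distribution.

One subtlety worth stating: rescaling one sample's counts by `c` rescales its
size factor by `c` *relative to the others*, but the median-of-ratios
geometric-mean reference also shifts, so all normalized counts move by a
common factor and transformed values agree only up to a common additive
constant. All consumers of the VST matrix are invariant to that constant.

## Differential accessibility

Each region is fit by an NB GLM with log link and `log s_j` offset; IRLS with
expected-information weights `mu/(1 + alpha mu)`, convergence at
`max|dbeta| < 1e-8`, at most 100 iterations. Separation (an all-zero group) is
handled by damping non-intercept terms with a ridge of 1e-6 only when the
undamped update diverges; rows that still fail are flagged (NaN statistics)
rather than raised. The contrast coefficient is tested with a two-sided Wald
test against the standard normal (the convention of the reference
implementation), and p-values are Benjamini–Hochberg adjusted across regions.
Categorical covariates are treatment-coded with the alphabetically first
observed level as reference; log2 fold changes are natural-log coefficients
divided by `ln 2`, oriented as non-reference level vs reference. No
independent filtering or outlier-distance handling is applied; at synthetic
scale these affect power, not validity.

## Variance partitioning

Per region, transformed accessibility is fit to a linear mixed model with
random intercepts for categorical covariates and fixed effects for continuous
ones, by direct REML: the restricted log-likelihood is maximized over
log-variances with L-BFGS-B from three method-of-moments-flavored starts,
then polished with a derivative-free Nelder–Mead pass (the balanced one-way
oracle agreement of 1e-4 drives this tolerance). The response is standardized
before fitting (fractions are invariant to affine rescaling). The reported
fraction for a random covariate is its component variance over the total; for
a fixed covariate it is the sample variance of the fitted term (the convention
of the variance-partitioning tools used for such cohorts); the residual closes
the sum to exactly one. Note the two-level-factor subtlety: a factor with
levels `+d/-d` has component variance `2 d^2` (k-1 denominator), which is the
convention used when "a covariate explains X% of variance" is quoted.

## Progression predictor

The ALSFRS-R-slope predictor follows a staged procedure on the VST matrix
restricted to regions within 2 kb of a TSS and to ALS cases with a recorded
slope: (1) drop samples flagged by a guarded two-cluster cut of the
inter-sample correlation matrix (complete linkage on Euclidean distances
between correlation columns; the smaller cluster is excluded only if it holds
< 20% of samples *and* its mean off-diagonal correlation is lower than the
larger cluster's by at least 0.1 — without that margin the rule would trip on
any homogeneous cohort); (2) drop slopes beyond 1.5 IQR outside the quartiles
(type-7 quantiles, single pass); (3) drop samples from differentiation batches
with fewer than 4 representatives *in the remaining set*; (4) split 90/10 into
train/test, stratified by batch, test size `ceil(0.1 n)`, fixed across reruns.

Feature selection is LASSO — objective `(1/2n)||y - b0 - Xb||^2 + lambda||b||_1`
on internally standardized predictors, unpenalized intercept — solved by
cyclic coordinate descent with soft-threshold updates, an active-set strategy
with vectorized KKT screening, and warm starts along a 100-point log-spaced
path from `lambda_max` down to `lambda_max/1000`. `lambda` is chosen by
ten-fold cross-validation (fold assignment by seeded permutation, sizes within
one); the default rule is minimum mean CV MSE, with the one-standard-error
rule available behind a flag. CV path fits run at coefficient tolerance 1e-4
with capped sweeps — the CV MSE curve is insensitive to coefficient error far
below the noise scale — while final fits use 1e-7. The selection is rerun many
times (default 1000) with fold reassignment; regions selected in more than
half of *all* runs (including empty-support runs; a flag switches the
denominator to non-empty runs) form the majority-vote set. Each run's support
is refit by OLS and evaluated on the fixed test set with the test R^2 anchored
at the training mean (`R^2 = 1 - SS_res / sum (y_test - mean(y_train))^2`), so
a constant predictor at the training mean scores exactly zero; the squared
correlation between prediction and truth is reported as a secondary metric.

A structural caveat, measured explicitly in the benchmarks: with ~25 true
predictors among ~2,000 candidates at n_train = 140, any lasso solution that
retains the true features carries a shrinkage-leakage component of scale
`lambda sqrt(k/n)` in its KKT residual, which recruits on the order of 17+
false features at any lambda (threshold-to-leakage ratio at most
`sqrt(n/k) ~ 2.4` sd). Majority voting over fold reassignment cannot remove
them, because for fixed training data a feature's selection depends only on
whether the chosen lambda is below its entry point. The practical consequence
is that majority-set precision saturates near 0.25–0.6 in this geometry —
the procedure finds the drivers (recall is high) but cannot certify them
exclusively. The benchmark reports the measured precision rather than hiding
it. A second consequence of the same geometry: because the false features
absorb driver weight, held-out MSE improves far less than the training fit
suggests, the mean CV curve can be flat within fold noise, and — depending
on the cohort realization — a large share of the reruns may select nothing
at all (the same behavior real cohorts show, where a tenth of reruns
returned an empty support). Aggregate metrics are therefore reported over
the non-empty runs, with the non-empty count alongside.

## Cis peak–gene mapping

All same-chromosome (gene, region) pairs with |region center − TSS| within
250 kb are tested. Expression and accessibility are each residualized on the
covariate design (intercept + FRiP, sequencer, case status, sex, PBMC type;
missing categorical levels become their own level so samples are not dropped)
and the residual slope is tested with `df = n − p_cov − 2`; by
Frisch–Waugh–Lovell this equals the joint-regression coefficient, verified to
1e-10 in tests. Bonferroni correction uses the number of pairs actually
tested (after pairing and an `sd > 1e-8` variance filter applied for numerical
safety only). Significant pairs are classified by sign, promoter proximity
(|distance| < 2.5 kb), and dual-sign peaks (a region positively associated
with one gene and negatively with another).

## QC statistics

The chrX reads-not-in-peaks statistic is
`(chrx_reads − chrx_reads_in_peaks) / total_reads`; in females the silenced X
contributes background fragments outside peaks, roughly doubling this value
relative to males. The female/male comparison is descriptive, with a
two-sided Mann–Whitney test attached. PCA is a column-centered SVD with
samples as observations; the most-variable-region selection breaks ties by
region id. Missing PBMC-type labels are imputed by a k = 15 majority vote in
the top-2 PC embedding of the 100 most variable regions (ties fall back to
the single nearest neighbor); the embedding is a deliberate simplification of
nonlinear embeddings used for the same purpose — the accepted check is label
recovery accuracy, not embedding geometry.

## Synthetic cohort generator

The generator is first-class, tested code. The desk-scale default is 220
samples (190 ALS / 30 HC; 27 C9-positive and 112 verified-negative cases,
matching the group sizes at which the C9 contrast is quoted) over ~5,000
regions and 1,000 genes — each gene carries two promoter regions within 2 kb
of its TSS (2,000 TSS regions total) and one distal region, with effect-class
blocks on dedicated chromosomes. Planted effects (log2 scale): chrY regions
at −8 in females; an XIST-like escape block at +4 in females; ±1.2 autosomal
sex regions; TCR-like regions at −3 in T-cell-derived samples plus ±0.5–1
memory regions; ±0.8 ancestry regions (a third more accessible in the
minority ancestry); a C9-like promoter block at −0.6 in repeat-expansion
carriers; ±0.3 weak case-status regions; ±0.4 sequencer regions; FRiP-coupled
regions at 4 log2-units per unit FRiP; and N(0, 0.3) per-batch shifts on a
block of regions. Dispersions follow `3/mu + 0.05` with log-normal scatter
(sd 0.3); depth factors are log-uniform over [0.5, 2].

ALSFRS-R slopes are generated in a second pass so the progression signal is
*exactly* linear in measured accessibility: 25 promoter driver regions are
drawn, their realized `log2(K/s + 1)` values standardized, and
`slope = −0.8 + c·z + eps` with `||c|| = 0.5` (signs random, magnitudes
within ±20%) and `eps ~ N(0, 0.1)`. The planted signal therefore explains
~96% of slope variance — deliberately stronger than real cohorts, where
chromatin explains far less — because the stability-selection recovery
experiment needs an identifiable target at desk scale; the generator is not a
claim about effect sizes in patients. Filter-chain pathologies are planted
exactly: 12 decorrelated samples (their region profile is a permutation of
the baseline), 6 extreme slopes placed far outside the 1.5-IQR fences, and 6
samples in two under-filled batches, so the eligible 180 slope-carrying cases
reduce to 156 retained and a 140/16 split.

Expression for a matched subcohort (80% of samples) is Gaussian around
per-gene baselines with mild sex/FRiP structure; 60 planted cis links tie a
gene's expression to a standardized accessibility track with slopes
±(0.8–1.6) (a third negative), and 10 dual-sign peaks link one region to two
genes with opposite signs. Per-sample peak calls for the consensus stage open
each true region in 30–95% of samples (jittered boundaries) and decoy regions
in ~3%, so the 10% occupancy threshold reproduces exactly the true catalog.

What the generator does *not* emulate: fragment-level structure (no reads,
fragment lengths, or TSS-enrichment profiles), genuine co-accessibility
correlation between regions, linkage between ancestry and genotype, and any
nonlinearity in the clinical signal. Passing recovery tests therefore shows
the *procedures* are implemented correctly and calibrated under the stated
model; it does not certify performance on real cohorts.

## Problem sizes and tolerances

Benchmarks run at the sizes stated above: differential calibration over the
full ~5,000-region cohort; variance-partition oracle checks on balanced
synthetic designs (n = 96–200); stability selection with 100 fold-reassignment
reruns (the selection-frequency machinery is identical at any rerun count; the
rerun count only narrows the standard error of the aggregate metrics);
co-expression over all ~47,000 cis pairs of the cohort. Exact arithmetic
checks (size factors on proportional columns, KKT/OLS/soft-threshold
identities, FWL) are asserted at 1e-6 to 1e-12; distributional checks
(type-I error, FDR, coverage) at Monte-Carlo-appropriate windows; recovery
checks at the tolerances the planted effect sizes support.
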