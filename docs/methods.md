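# Methods

`dystromon` implements the statistical machinery for monitoring dystrophic
muscle disease from blood RNA-seq: four analysis engines (cross-sectional
moderated linear models, longitudinal precision-weighted mixed models,
co-expression network integration, and negative-binomial quasi-likelihood
models) plus a synthetic-data generator that plants known effects so every
engine has a parameter-recovery test surface.  This note records the models,
the defaults and why, the numerical choices, and the known limitations.

## Filtering and normalization

Genes are kept when they reach at least `min_cpm` counts per million in at
least `ceil(min_frac * n)` samples, computed on raw library sizes.  Defaults
are 5 cpm in 10% of samples for differential expression and a stricter
10 cpm in 40% for network estimation (networks need stable correlations, so
they get the harder floor; `network.check_network_filter` refuses matrices
that were only filtered at the looser threshold).  The ceiling rule reads
"at least 10% of samples" as a lower bound on a *count* of samples.

Between-sample scaling uses the trimmed mean of M-values.  For each sample
against a reference (the sample whose 75th-percentile cpm is closest to the
mean of those percentiles), gene-wise log2 expression ratios M and average
log2 abundances A are formed over genes expressed in both samples; the top
and bottom 30% by M and 5% by A are discarded (rank-based, stable ties) and
the remaining M values averaged with inverse delta-method-variance weights.
Factors are rescaled to geometric mean one.  All-zero genes are dropped
before the reference choice so that padding a matrix with unexpressed genes
is a no-op.  log2-cpm uses pseudo-counts 0.5 (numerator) and 1 (library) so
zeros are finite and results bit-reproducible.

## Precision weights

Per gene, ordinary least squares on the analysis design gives a residual
standard deviation and an average log2-count; a lowess fit (span 0.5, three
robustifying iterations) of the square-root standard deviation on average
log2-count is the mean-variance trend.  Each observation's weight is the
trend prediction at its fitted log2-count, floored at 1e-3, raised to the
power -4 (an inverse-variance weight for log2-cpm).  The trend is fitted
once per dataset and re-estimated for each analysis design matrix; weights
are invariant to gene-wise location shifts by construction.

## Cross-sectional differential expression

Gene-wise weighted least squares against one shared design (all four mouse
groups in a single model, pairwise contrasts from the shared fit so every
contrast uses the same variance estimate).  Residual variances are moderated
by empirical Bayes: the distribution of log s^2 is moment-matched to a
scaled log-F using closed-form digamma/trigamma identities (Newton inversion
of the trigamma function), giving a prior (d0, s0^2) and posterior variances
(d0 s0^2 + d s^2)/(d0 + d).  When the observed spread of log s^2 does not
exceed the chi-square sampling component, d0 is infinite and all variances
shrink to the common value; exactly identical inputs shrink to that value
without the chi-square bias correction (degenerate input, not a sample).
Contrasts are tested with moderated t (1 df) or moderated F on d + d0
denominator degrees of freedom; BH is applied within each contrast (the
contrasts answer separate questions and are reported separately).

## Longitudinal mixed models

Per gene: y ~ N(X beta, sigma_b^2 Z Z' + sigma^2 W^{-1}) with a subject
random intercept and voom weights W.  The fixed effects are intercept +
time (categorical, first week reference) + group + group x time; the null
model drops all group terms, so the LRT has 1 + (T-1) degrees of freedom.
ML (never REML) is used whenever likelihoods of different fixed-effect
structures are compared, and the implementation refuses an LRT on REML fits.

The likelihood is maximized by analytic profiling rather than generic
optimization: for a fixed variance ratio lambda = sigma_b^2/sigma^2 the GLS
coefficients and sigma^2 are closed-form, and every per-subject block inverse
is a rank-one Sherman-Morrison update, so the profile likelihood in lambda
is evaluated with pure vector arithmetic for all genes at once.  lambda is
maximized on {0} plus a 61-point log grid spanning 1e-6..1e4 followed by a
ternary search inside the winning bracket (60 iterations, deterministic);
a refinement is kept only where it does not lose likelihood.  With one
observation per subject the ratio is unidentifiable and is fixed at 0 with a
warning.  Single-gene fits agree with statsmodels MixedLM (ML) to ~1e-4 on
coefficients; that cross-check lives in the test suite, not the engine.

Testing is two-stage: the LRT (chi-square reference) screens genes at FDR
0.05, then per-week Wald z-tests on the screened genes localize the weeks;
per-week BH is computed within the screened set, and a "significant at week
w" list means LRT FDR < 0.05 AND week-w Wald FDR < 0.05.  The Wald reference
is standard normal, matching the plain Wald test; the per-week logFC at the
reference week equals the group main effect by construction.

Calibration caveat: the fixed-effect ML LRT against chi-square is known to
be anti-conservative in small samples.  At 5 vs 5 subjects x 5 weeks
(50 observations, 5-df test) the measured empirical size at alpha = 0.05 is
about 0.09-0.12, consistent with the classical n log(RSS0/RSS1) analysis;
it falls to ~0.06 by 20 subjects per group and to nominal beyond.  The
chi-square reference is retained because it is the test this pipeline
defines; users with few subjects should read borderline LRT p-values
accordingly.

## Co-expression networks and integration

Unsigned adjacency |cor|^beta with beta the smallest candidate power whose
scale-free fit R^2 reaches 0.8 (fallback 6 with a warning — small planted
simulations rarely look scale-free, which is expected).  The topological
overlap matrix rewards shared neighbors; modules are branches of an
average-linkage tree on 1 - TOM cut at a fixed height, clusters under 30
genes go to "grey", and modules whose eigengenes correlate at or above 0.75
are merged most-correlated-pair first.  The static cut height defaults to
0.95: at 0.99 background genes attach to planted modules (mean adjusted Rand
index 0.48 on two 60-gene modules at loading 0.9), while 0.95 recovers them
cleanly (ARI ~0.88) and still leaves pure-noise runs fully grey.  The cut is
static rather than the dynamic hybrid algorithm — a deliberate
simplification that is deterministic and sufficient for planted-structure
recovery; module *counts* on real data are cut-parameter-dependent and are
not a supported readout.  Color labels follow the conventional sequence by
decreasing size and carry no meaning beyond display.

Module eigengenes are the first right singular vector of the gene-z-scored
expression, oriented so the mean member correlation is non-negative; kME is
a gene's correlation with its own module's eigengene, and hubs are the top-5
by kME (or a kME threshold).

Integration computes: Jaccard and overlap coefficients for all module pairs
on the intersected gene universe (grey excluded); a community-structure
validation (CSV) index defined here as 100 x the fraction of within-module
edges of the native network that are also edges of the foreign network,
after binarizing both networks at the same edge-density quantile (default
top 5%; a degenerate all-equal adjacency yields no edges, not all).  This
operationalization is isolated behind one function so an alternative formula
can be substituted without touching callers.  Eigengene cross-correlations
over matched samples use Pearson r with the t-transform p-value, BH across
all pairs, and a display flag at |r| > 0.5; the hub "remote sensor" scan
correlates each blood hub with each muscle eigengene, BH across all tested
pairs.

## Negative-binomial quasi-likelihood engine

Counts are NB with Var = mu + phi mu^2 and log link with offsets
log(effective library size); reported logFCs are log2.  Gene-wise
dispersions maximize the Cox-Reid adjusted profile likelihood (the NB
log-likelihood at the IRLS fit minus half the log-determinant of X'WX) on a
41-point log grid over [1e-4, 4] with warm-started IRLS, refined by 25
deterministic ternary steps; below 1e-6 the likelihood and deviance switch
to their Poisson limits.  A lowess trend (span 0.3) of log dispersion on log
mean cpm gives the trended dispersion used for the final fit.  Gene-wise
quasi-dispersions (deviance / residual df) are squeezed by the same
empirical-Bayes F moment matching as the linear engine; the QLF statistic is
(deviance drop / q) / squeezed s^2 against F(q, prior + residual df),
reducing to a scaled chi-square when the prior df is infinite.  IRLS adds a
1e-10 ridge and clips the linear predictor at +-30 so all-zero groups stay
finite (flagged); non-converged genes get NaN p-values and leave the BH
pool.

The treatment analysis takes a pre-specified disease gene list and its
disease logFCs, drops list genes failing the expression filter (reporting
both counts), fits the three-arm model, runs the omnibus QLF then the
pairwise arm contrasts, and scores concordance: a gene is concordant when
both arms' estimated logFC signs equal the sign of the desired effect, the
negative of the disease logFC.  Because both treated arms are contrasted
against the same saline arm, the chance concordance level is not 1/4 but
the bivariate-normal orthant probability 1/4 + arcsin(rho)/(2 pi) with rho
the shared-control correlation (~1/3 at these arm sizes); the test suite
checks against that quantity.

The cohort analysis codes steroid as 0 for every healthy subject (treatment
is nested in patients), centers age, and fits intercept + group + age +
age x group + steroid.  The omnibus QLF covers {group, age x group, steroid}
(3 df, interaction included because both the baseline group effect and its
age trend are reported; a flag drops it); within omnibus-significant genes
the group test covers {group, age x group} and the steroid test {steroid}.
Covariate blocks are summarized by the first PC of the standardized block
(complete subjects only), oriented by a positive anchor-variable loading;
PC association fits each gene against the PC as sole covariate, matching the
companion analysis (an age-adjusted variant is a one-line design change).

## Synthetic data

The generator emulates the four study designs at desk scale with 2,000 genes
by default: baseline log2-cpm ~ N(5, 1.5^2), gene dispersions log-normal
(median 0.1, log-sd 0.5), library sizes log-normal (median 2e6, log-sd 0.3),
counts Gamma-Poisson.  Planted structure:

- cross-sectional muscle (31 samples: 7 healthy + 8/8/8 dystrophic): 150
  disease genes at logFC +-2 shared by all dystrophic groups — the
  conservation of the signature across models is a study phenomenon the
  drivers reproduce;
- paired blood for the same subjects, coupled through shared latent module
  factors attenuated by a per-module rho (defaults 0.8, 0.8, 0.6, 0, -0.6:
  shared, weakly shared, independent and anti-correlated pairs), rather than
  by copying expression — this reproduces eigengene cross-correlation
  without identical membership;
- longitudinal blood (4 groups x 5 subjects x weeks 6-30): per-week disease
  logFC profile (2, 1, 1, 0.3, 0.2) mirroring the early-regeneration decline,
  and gene-specific subject random intercepts (sd 0.5, a free simulation
  parameter — the study reports no blood variance components) constant
  across a subject's weeks.  A subject intercept *shared across genes* would
  be a library-size effect and vanish under TMM, so intercepts are drawn per
  gene x subject;
- treatment (saline 4, PMO-like 5, PS49-like 5, all dystrophic): treated
  arms move by -kappa x disease logFC (defaults kappa = 0.3 and 0.05,
  a moderate and a minimal restoration), plus a +2 logFC side-effect
  signature in the PS49-like arm on 30 genes drawn from the disease set
  (side effects hit disease-dysregulated interferon-like genes, which is
  what makes them visible inside the pre-specified gene list);
- human cohort (18 healthy + 39 patients, 32 on steroids): 300 disease genes
  at logFC +-1.5, an age x group slope of -0.1/yr pulling effects toward
  baseline, a 40-gene steroid signature opposite in sign to the group
  effect, and two covariate blocks built as single-factor models with equal
  loadings a = sqrt((p tau - 1)/(p - 1)) chosen in closed form so the
  population first-PC share is tau (0.70 for 24 body measurements, 0.78 for
  12 physical tests); one designated gene tracks the physical-test factor
  at 0.3 log2 units per factor sd.

Every generator is a pure function of (design, seed); ground truth is
recorded before noise.  What the generator does *not* emulate: batch
effects beyond library size, gene-gene correlation outside planted modules,
count-length biases, missing longitudinal samples, or annotation ambiguity —
so passing recovery tests demonstrate correctness of the estimators under
the assumed model, not robustness to real-data artifacts, and the study's
absolute gene counts are not reproduction targets.

## Problem sizes and defaults

Simulation-backed checks run at 2,000 genes for calibration (binomial error
~0.005 at alpha 0.05), 500 planted genes for recovery averages, 300-gene
networks over 30-100 replicates for structure recovery, and the study's
sample sizes everywhere (5v5 x 5 weeks; 4/5/5 arms; 18 + 39 subjects).
These sizes keep every estimate's Monte-Carlo error well below the
tolerances being checked.  The single integer seed (default 13154) drives
all randomness; scripts derive sub-seeds deterministically.
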