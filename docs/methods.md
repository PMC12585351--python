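# Methods

## The model

`asepop` models population-level allele-specific expression (ASE) from
bulk RNA-seq allele counts alone — no genotyping data. For one SNP, each
sample contributes a reference/variant count pair `(x_r, x_v)`,
`n = x_r + x_v`. The reference count is modeled as a three-component
beta-binomial mixture over latent genotypes:

    P(x_r) = phi_rr * BetaBin(x_r | n, pi = 1 - SE, rho = rho_hom)
           + phi_rv * BetaBin(x_r | n, pi = pi_het, rho = rho_het)
           + phi_vv * BetaBin(x_r | n, pi = SE,     rho = rho_hom)

with mixture weights `(phi_rr, phi_rv, phi_vv)` acting as genotype
frequencies. Two parameterizations of overdispersion are used
interchangeably: `theta` in `[0, inf)` and `rho = theta / (1 + theta)` in
`[0, 1)`; `theta = 0` recovers the binomial.

The parameters of scientific interest live in the heterozygote component:

* `pi_het` — **allelic bias** (AB): the mean reference-allele fraction of
  heterozygotes. Shifts capture cis-regulatory variation and technical
  reference bias.
* `rho_het` — **allelic dispersion** (AD): how variable heterozygotes'
  allelic fractions are across the population, beyond binomial sampling.
  Clonally amplified allele-specific dysregulation (imprinting-like
  silencing, amplified cis effects) inflates AD.

**Differential allelic dispersion (dAD)** asks whether `rho_het` differs
between a control and a case cohort: the alternative model gives each
group its own `rho_het` through a per-sample group indicator, all other
parameters shared.

Assumptions worth stating: exactly two alleles per SNP; one global
sequencing-error rate `SE` applies to every locus; homozygote
overdispersion `rho_hom` is a per-SNP nuisance shared by both homozygote
components and both groups; samples are independent given their genotype;
genotype frequencies need not obey Hardy–Weinberg (HWE is used only as a
downstream quality filter, adjusted by a cohort inbreeding coefficient).

## Metaparameters

`SE` and the inbreeding coefficient `F_inbr` are estimated cohort-wide
before any dAD fitting, from a deliberately crude binomial version of the
mixture (heterozygote fraction pinned at 0.5, no overdispersion), which
has closed-form EM updates and is therefore cheap enough to fit to every
locus. Loci with implausible fits are discarded (estimated `SE < 0.035`,
more than 40 covered samples, median coverage >= 10, minor-allele count
fraction >= 0.15) and the medians of the surviving per-locus `SE` and
`F = 1 - phi_rv / (2 (phi_rr + phi_rv/2)(phi_vv + phi_rv/2))` estimates
are kept. Controls and cases are pooled here (the model has no group
structure); both values can instead be supplied by the user. We recommend
not forcing `SE` below ~0.002: a tiny error rate makes the homozygote
components too rigid during EM sample assignment.

## Fitting

EM alternates genotype responsibilities (E-step) with closed-form updates
of the mixture weights and quasi-Newton ascent for the continuous
parameters (M-step), on transformed coordinates `logit(pi_het)`,
`log(theta_het)` (one or two of them), `log(theta_hom)` — unconstrained
optimization on the transformed scale proved more reliable than bounded
methods. Starting values for `(pi_het, theta_het)` come from
Kleinman-type moment estimators on putative heterozygotes (samples with
reference fraction in `[0.15, 0.85]`), generalized to unequal totals,
with unit weights (the ideal weights for `theta = 0`; they are only
starting values, the likelihood refines them). Non-positive moment
estimates of `theta` are clamped to `1e-6`.

A beta-binomial is bimodal when `theta > max(pi, 1 - pi)`; a bimodal
heterozygote component almost always means the optimizer is using it to
absorb homozygote data. Fits that end in that region are rerun with the
unimodality constraint imposed (SLSQP on the same objective); accepted
fits always satisfy the constraint.

Convergence: relative log-likelihood change below `1e-8`, at most 200 EM
iterations; the log-likelihood is checked to be non-decreasing every
iteration. Degenerate inputs (essentially no heterozygote mass) yield a
fit flagged `unidentifiable` rather than an error.

### Numerical kernel

The PMF is evaluated through `betaln`/`gammaln` (fast, vectorized). For
extreme parameter values the two log-beta terms can cancel
catastrophically; when their relative gap falls below `1e-8` the kernel
switches to an exact log-space evaluation of the rising-product form
(O(n), no cancellation), then — for totals too large for the product —
to extended-precision evaluation (mpmath, escalating to a configurable
cap of 2048 bits), and as a last resort to the plain binomial PMF. Every
escalation increments a counter on the precision policy; nothing falls
back silently. Gradients use analytic digamma expressions in the
interior and finite differences at parameter boundaries.

### Outlier handling

Leave-one-out influence deltas on `(pi_het, theta_het)` are computed per
group; a sample is an outlier when either delta exceeds 5 sample
standard deviations of its delta series (identical samples give zero SD
and no flags). Flagged samples are excluded from all fits and tests but
retained for HWE assessment — outliers are heterozygote-enriched, so
removing them there would bias the genotype-frequency test. Two caveats
the tests document: a sample that looks like a clean homozygote is
absorbed by the homozygote component rather than flagged (it simply has
no leverage on the heterozygote parameters), and with the outlier's own
delta included in the SD the rule only has power in groups larger than
~26 samples. Because the procedure refits the mixture once per sample it
is expensive; it is on by default in the pipeline and can be disabled in
`RunConfig`.

## Testing for dAD

Per SNP, the reported P value is a likelihood-ratio test between the
shared-dispersion and group-specific-dispersion fits on the same
(non-outlier) samples, referred to chi-square with 1 df. The LRT is
unreliable against boundary nulls such as `theta = 0`; fits with a
dispersion at the clamp floor are flagged, not corrected.

Inside permutations a **score test** replaces the LRT: the null model has
no group-specific parameter, so its fit is identical under every
relabeling and is computed once; only the score vector and information
matrix depend on the labels. The statistic is the quadratic form of the
score in the inverse information over
`tau = (pi_het, rho_hom, rho_het_control, rho_het_case, phi_rr, phi_rv)`,
with both group dispersions sitting at the shared fitted value.
Derivatives are central finite differences on the natural `rho` scale
with per-parameter steps `0.01 * max(|tau_t|, 0.05)` clipped to the
domain.

Two numerical choices matter here and were made after direct comparison
against the LRT:

* **Expected, not observed, information.** With the observed Hessian the
  quadratic form occasionally exploded (statistics ~100 where the
  permutation LRT was ~1) through spurious profiling across a
  near-singular `rho_case`/`rho_hom` curvature block — observed
  information is not positive definite away from quadratic behavior. The
  engine instead accumulates the expected (Fisher) information per
  sample by enumerating the count support under the fitted null mixture;
  it is PSD by construction and restored rank correlation with the LRT
  to ~0.99 on the affected data.
* **Restricted-score structure.** At the exact restricted MLE all score
  components vanish except the antisymmetric dispersion contrast, so the
  engine projects the finite-difference gradient onto that contrast
  before forming the statistic. Without this, EM convergence noise in
  nuisance coordinates leaks through the matrix inverse and visibly
  degrades agreement with the LRT. The full per-parameter score vector
  is still reported.

A stencil engine precomputes all per-sample quantities once per SNP, so
one permutation's score test costs two (13, S) matrix-vector products, a
(36,)-vector contraction and a 6x6 solve. An information matrix with
condition number above `1e12` raises `SingularHessianError`; the
permutation loop treats that as a redo.

The score test is anchored at the null fit, so it tracks the LRT tightly
under the null and local alternatives and saturates under distant ones
(agreement drops to rank correlation ~0.9 at a 12-fold dispersion
contrast); it is used only where P values near uniformity matter — the
permutation covariance estimate — never for reported effect estimates.

## SNP filters and gene-level combination

Before combination a SNP must have: median total count >= 4 in both
groups; estimated heterozygote count (responsibility sums) >= 12 in both
groups for autosomal SNPs, >= 8 on the X stratum; fitted
`0.05 <= pi_het <= 0.95`; and both groups consistent with HWE (chi-square
frequency test of the per-group EM genotype counts against
inbreeding-adjusted proportions, 1 df, pass if P > 0.001). SNPs map to
genes through an annotation table with the hierarchy exonic > UTR /
noncoding transcript > intronic / splice > up-/downstream; SNPs tied
between genes at their best level, or unannotated, are dropped.

Per gene, P values are combined with the Lancaster statistic
`T = sum_i G^{-1}_{w_i/2, 2}(1 - p_i)` (inverse gamma CDF, i.e. chi-square
quantiles with `w_i` df). Weights are the limiting group's
(heterozygote count x median total count), rescaled to sum to twice the
number of SNPs, which makes equal weights reduce exactly to Fisher's
method. P values are floored at `1e-15` before the inverse transform.

Nearby SNPs share reads and molecules, so their P values are positively
dependent and the naive chi-square reference is anti-conservative. The
correction rescales: `c*T ~ chi2(v)` with `v = 2 E[T]^2 / var(T)`,
`c = v / E[T]`, `E[T] = sum w_i`,
`var(T) = 2 sum w_i + 2 sum_{i<j} Covar_ij`. The covariances are
estimated from label permutations shared across the gene's SNPs (default
10,000; the simulation suite uses 500): each iteration shuffles the
control/case labels once, computes every SNP's score-test P from its
precomputed null fit, and transforms it through that SNP's inverse-gamma
map; the empirical covariances of these transforms, negatives truncated
to zero (negative read-sharing dependence is biologically implausible),
give the correction. A permutation is redone when any SNP is left with
<= 6 putative heterozygotes (by the per-group fits) in either group, or
on a singular information matrix; a gene exceeding the redo budget is
skipped with a warning. Permutation streams are seeded per gene
(master seed + CRC32 of the gene id), making results reproducible and
independent of gene ordering.

Gene-level dispersion and coverage summaries are weighted means of the
per-SNP values with group-matched weights
`sqrt(n_het * median count)`. Benjamini–Hochberg correction is applied
within each stratum (autosomal and X) separately; the X stratum is
declared by a user-supplied gene list and female-sample subset, never
inferred.

## Canonical dAD

For case samples classified heterozygous with total count > 20, a
sample's contribution to increased dispersion is the inverse of its
minimal tail area under the fitted case heterozygote component:
`1 / min(CMF(x_r), 1 - CMF(x_r) + PMF(x_r))` (the PMF term puts the two
discrete tails on an equal footing). "Canonical" dAD — silencing of one
allele that also reduces output — predicts a negative Spearman
correlation between this contribution and the sample's total count.
Spearman uses midranks; for <= 9 pairs the P value is computed by exact
permutation enumeration. Per gene, P values are Holm-corrected across
SNPs and the smallest adjusted P is reported; ties go to the SNP with
the larger combination weight, then the lexicographically smaller id.

## Synthetic cohorts

The generator draws, per sample: a genotype from inbreeding-adjusted
Hardy–Weinberg proportions; a total count from a gamma–Poisson (negative
binomial) coverage model with mean 50 and shape 2 by default, floored at
1; and a reference count that is beta-binomial given the genotype —
homozygotes at `1 - SE` or `SE` with dispersion `rho_hom`, heterozygotes
around `pi_het` with the group's `rho_het` through a latent Beta
fraction. Defaults emulate a bulk case/control cohort: 72 controls vs
268 cases, reference-allele frequency 0.3, panmixia, `SE = 0.002`,
balanced heterozygotes with `rho_het = 0.03`.

Multi-SNP genes share one genotype vector (tight linkage at gene scale)
and one per-sample depth factor (the gamma mixing variable — coverage at
nearby SNPs comes from the same reads). A `correlation` parameter
couples allele counts across SNPs: with probability `correlation` a
sample's SNP reuses the gene-shared latent fraction *and* draws its
reference reads from a shared per-sample read pool (binomial pool,
hypergeometric subsets), so at correlation 1 with equal totals the SNPs'
observed counts are identical — the fully dependent limit in which the
Lancaster correction must collapse the effective degrees of freedom to a
single SNP's. The "loss" dAD mechanism multiplies the totals of skewed
case heterozygotes (|fraction - pi_het| > 0.25) by 0.5, coupling allelic
extremity to reduced expression for canonical-dAD testing; "gain"-type
dAD is expressed simply as a larger case `rho_het`.

What the generator does *not* emulate: read-level artifacts (mapping
bias, duplicates), per-locus error-rate variation, tumor purity as an
explicit mixture, copy-number segments, and LD decay beyond a gene.
Passing simulation tests therefore demonstrates correctness of the
statistics under the model's own assumptions, not robustness to
alignment artifacts.

## Simulation scales used by the test suite

Property checks run at desk scale, chosen to keep the default suite
within a laptop-class budget while leaving Monte-Carlo noise well below
the tested margins: cohorts of 300 samples; 100 cohorts for estimator
recovery (median |rho error| < 0.015); 1,000 null SNPs for type-I error
(observed ~0.05–0.06); 200 replicates for power at a 0.02 vs 0.25
contrast (observed 1.0); 300 three-SNP genes at read correlation 0.8
with 500 permutations for combined-P calibration (corrected KS ~0.07
versus uniform; uncorrected rejection ~0.10 at nominal 0.05,
demonstrating why the correction exists); 20 pipeline runs of 25 genes
for planted-effect ranking. The canonical-dAD scenario uses coverage
shape 10 (moderate depth variability): its signal is itself a coverage
effect, and under the default shape-2 model depth noise swamps the
two-fold coverage halving that the loss mechanism plants — a genuine
power limitation of the statistic worth knowing about, not a numerical
issue.

## Known limitations

* Two alleles per SNP; no haplotype phasing; no per-locus error rates.
* The LRT P value is asymptotic; very small heterozygote counts (below
  the n_het filter) are not protected beyond the filters.
* The covariance correction transfers score-test dependence estimates to
  LRT P values; residual miscalibration of a few percent at the 0.05
  level remains under strong inter-SNP dependence.
* Leave-one-out outlier detection costs one refit per sample per group.
* The canonical-dAD correlation has low power when expression depth is
  highly variable across samples.
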