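# Methods

## Model

For a quantitative trait measured on `n` related individuals the package
fits the variance-component model

    y = X beta + g + gxe + eps,
    g   ~ N(0, sigma2_g   * A),
    gxe ~ N(0, sigma2_gxe * A_E),
    eps ~ N(0, sigma2_e   * I),

where `A` is the genomic relationship matrix (GRM) and `A_E` is the GRM
restricted to pairs of individuals in the same exposure group.  Heritability
fractions are defined against the total fitted variance:
`h2(g) = Vg / (Vg + Vgxe + Ve)`, `h2(gxe) = Vgxe / (Vg + Vgxe + Ve)`, and
the total `h2(g+gxe)` is their plain sum.  Several GxE kernels (one per
exposure) may enter a single fit; each contributes its own component.

### GRM

`A_jk = (1/m_jk) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i))` over
SNPs non-missing in both individuals, with the finite-sample diagonal
`A_jj = 1 + (1/m_j) sum_i (x_ij^2 - (1+2p_i) x_ij + 2p_i^2) / (2p_i(1-p_i))`.
Allele frequencies `p_i` come from the **full sample**, matching common
GREML practice; QC statistics (MAF, HWE) deliberately use **founders only**
to avoid family inflation — the asymmetry is intentional.  Because sample
allele frequencies center the dosages, off-diagonal entries are deflated by
O(1/n) (row sums of the standardized matrix are constrained); tests on
relative-pair expectations account for this.  With the corrected diagonal
the GRM can be slightly indefinite, increasingly so for small SNP subsets;
all downstream algebra tolerates this (see REML below).

### GxE kernel

`A_E` is the Schur product of `A` with the same-group indicator matrix:
off-diagonals survive only within exposure groups, the diagonal equals the
base diagonal.  Continuous exposures are quartile-coded (ties to the lower
group) before kernel construction; smoking is a 3-level factor.  If every
individual shares one group, `A_E = A` and the GxE component is
statistically indistinguishable from additive variance — only the sum
`Vg + Vgxe` is then identified, which the test suite checks explicitly.

## REML estimation

The restricted likelihood (constants dropped) is
`-1/2 [log|V| + log|X'V^-1X| + y'Py]` with
`V = sum_c sigma2_c K_c + sigma2_e I`.  Numerical scheme:

* **AI-REML with EM warm-up**: the first 2 iterations are EM steps, then
  Newton steps with the average-information matrix.  Components are floored
  at `1e-6 x` phenotypic variance (constrained REML), keeping all `h2` in
  [0, 1].
* **Active set**: a component pinned at the floor whose score is negative is
  frozen out of that iteration's AI system.  Without this the solver crawls
  near the boundary (observed: ~85 iterations instead of ~8 on null data).
* **Monotonicity**: AI steps are step-halved until the likelihood does not
  decrease, with an EM fallback; convergence requires a log-likelihood
  change `< 1e-8` and a component change `< 1e-6` relative to the
  phenotypic variance, capped at 100 iterations with up to 3 perturbed
  restarts.
* **Single-kernel fast path**: for `V = sigma2_g K + sigma2_e I` the model
  is rotated by the eigenvectors of `K` and the likelihood profiled to a
  one-dimensional search over the variance ratio (coarse grid + bounded
  refinement).  Eigenvalues are *not* clipped: for indefinite kernels the
  ratio search is bounded so `V` stays positive definite.  Both paths
  compute the same likelihood value, verified by a cross-path test and a
  brute-force grid-search oracle.
* **Nesting in practice**: the full (GxE) fit is warm-started from the
  reduced (additive-only) solution with a small GxE seed (2% of phenotypic
  variance), so monotone updates keep `logL_full >= logL_reduced` and the
  likelihood-ratio statistic is well defined.

Standard errors come from the inverse AI matrix at the solution;
heritability SEs use the delta method on the component covariance.

### GxE test

`LRT = 2(logL_full - logL_reduced)`, clipped at zero.  The default null is
the 50:50 `chi2_0`/`chi2_1` boundary mixture (`p = 0.5 P(chi2_1 >= LRT)`,
`p = 0.5` at `LRT = 0`); a pure-`chi2_1` option supports cross-checking
against software that uses that convention, and a one-sided Wald p-value on
the GxE component is always reported alongside, since published "nominal P"
values do not state which construction was used.

## GxE GWAS scan

Per SNP: `y = X beta + beta_E e + beta_s x + beta_int (x * e) + u + eps`
with `cov(u) = sigma2_u K`.  Variance components are estimated **once** on
the null model and reused for every SNP (two-step approximation): all
columns are whitened by the Cholesky factor of the fitted covariance and
each SNP reduces to a vectorized two-column regression with Wald tests.
The exposure enters the interaction as its ordinal quartile index 1..4
(single-df test; the parsimonious reading when one interaction p-value per
SNP is reported); a continuous-coding option exists, and the interaction
statistic is invariant to affine recoding `e -> a e + b, a > 0`.  An exact
mode re-estimates the variance ratio per SNP (eigen rotation) for
cross-checks on panels of at most ~2000 SNPs.  Monomorphic SNPs yield NA
rows.  Scan summaries report significant counts at the 1e-5 genome-wide
threshold, genomic-control lambda (median chi-square ratio), and QQ
coordinates.

## Bootstrap null for SNP-set estimates

Significant-SNP sets found by a scan are refit with a subset GRM; to ask
whether such an estimate could arise by chance, `n_sets` random SNP sets of
the matched size are drawn without replacement, each is fitted with the
identical subset-GRM + GxE model, and the null h2(gxe) and LRT-p draws are
summarized by nearest-rank percentiles.  The h2 reference is the upper 95th
percentile; the p-value reference is the 95th percentile *in the direction
of increasing significance*, i.e. the nearest-rank 5th percentile of the
null p draws — an observed p below it is more extreme than 95% of random
sets, which is the comparison the published tables make (observed p ~ 1e-23
against a reference of ~0.03).  Failed fits are excluded with a logged
count; more than 5% failures aborts.

## Multiple-testing correction

Li & Ji's spectral estimator
`M_eff = sum_i [I(lambda_i >= 1) + (lambda_i - floor(lambda_i))]` on the
exposure (and trait) correlation matrices, with Nyholt's
`1 + (M-1)(1 - var(lambda)/M)` reported as the alternative; a small
epsilon guards `floor` against eigenvalues like `4 - 1e-15`.  Effective
counts are rounded to integers before the Bonferroni product and the
corrected threshold is reported both raw and to one significant digit
(`0.05/(13*3) -> 0.001`).

## Synthetic data generator

The generator emulates a two-center family nutrition cohort:

* **Pedigrees**: independent three-generation families; a founding couple,
  their children plus married-in founders, and grandchildren.  Sibship
  sizes are `1 + Poisson(mean_sibs - 1)` (default mean 2.0); centers A/B
  are assigned at the family level.  The default desk scale is tens of
  families (hundreds of individuals); study-scale runs use ~100 families
  (~1000 individuals).
* **Genotypes**: unlinked biallelic SNPs gene-dropped through the pedigree.
  Founder allele frequencies are uniform on (0.05, 0.5) by default — wide
  enough to exercise the MAF filter only rarely, keeping desk-scale tests
  fast — founders are at Hardy-Weinberg proportions and each non-founder
  allele is a fair parental draw, so Mendelian consistency is exact by
  construction.  Missingness is iid at a configurable rate (default 0).
* **Exposures**: 14 continuous dietary/lifestyle factors (12 mostly as
  percent of total energy, plus glycemic load and physical activity scores)
  with a factor-model correlation structure (PSD by construction) whose
  strongest entry is r ~ 0.89 between n-6 PUFA and total PUFA, plus a
  3-level smoking factor (72/20/8%).  Within-family exposure correlation is
  a parameter, default 0, because the real-world value is not established.
  Quartile groups are assigned downstream by the preparation module, not
  baked into the generator.
* **Phenotypes**: generated under the exact estimation model.  Default
  mechanism is the direct kernel draw (multivariate normal from
  `sigma2_g A + sigma2_gxe A_E + sigma2_e I`), which makes recovery tests
  sharp; the alternative "causal" mechanism realizes the components through
  per-SNP effects on a designated causal set, with environment-group-
  specific effects for the GxE term (inducing the same covariance with the
  causal-subset GRM), and is used for SNP-set/bootstrap experiments.  The
  default four traits target additive heritabilities of 9-20% and GxE
  heritabilities of 24-39% on a unit total variance, the magnitudes the
  pipeline is designed to detect.  All generating values are recorded in a
  truth record; all randomness flows from one integer seed through
  deterministic sub-streams.

What the generator does **not** emulate: linkage disequilibrium beyond
family co-inheritance, assortative mating, realistic diet-questionnaire
error structure, or skewed raw trait scales (traits are generated directly
on the analysis scale, so Box-Cox is exercised on separately constructed
inputs).  Passing tests therefore demonstrate correctness of the estimation
machinery under its own assumptions, not robustness to model misspecification
in real cohorts.

## Numerical and design choices

* Missing dosages are NaN (no valid dosage doubles as a sentinel); GRM
  missingness is handled pairwise-complete with per-pair SNP counts stored
  in the interchange format's third column (1-based indices, lower
  triangle, gzip text).
* Quartile ties go to the lower group, making the coding deterministic,
  order-independent, and invariant to monotone transforms.
* Box-Cox lambda is profiled on a grid over [-3, 3] (step 0.01) with
  bounded refinement; non-positive values raise with guidance rather than
  being silently shifted.
* The HWE filter uses the exact conditional test (sum over heterozygote
  counts with probability <= observed), the well-defined choice at low
  counts; it is validated against full enumeration for every table with
  n <= 50.
* The Mendelian screen counts trio-impossible transmissions and
  opposite-homozygote duo conflicts; missing genotypes never count.  The
  default exclusion rule — errors in more than 1% of informative families —
  quantifies a "negligible errors" criterion that reports typically leave
  unstated, and is configurable.
* GRM principal components (top 3 by default) are eigenvector scores scaled
  by root-eigenvalue with a deterministic sign convention; BMI enters
  covariates only for the beta-cell-function trait by default, matching the
  covariate plans such analyses report.
* Quartiles are computed sex-pooled by default (a flag exists) since the
  original practice is unstated.

## Problem sizes used in the checks

Chosen as this package's desk-scale design points: variance-component
recovery uses ~1000 individuals x 5000 SNPs over 20 seeds; LRT calibration
uses ~500 individuals with 500 phenotype redraws on one fixed GRM (the LRT
null conditions on the kernels, so redrawing phenotypes is the standard
conditional simulation); the bootstrap contrast uses ~260 individuals,
a 1200-SNP panel, 49-SNP sets, and 200 null sets per repetition over 20
repetitions.  The acceptance script reruns smaller versions of the same
computations (5 recovery seeds, 200 null replicates, 5 bootstrap
repetitions x 100 sets).

## Known limitations

* Binary traits (liability scale) are out of scope; the variance machinery
  assumes continuous phenotypes.
* The two-step scan reuses null-model variance components per SNP; for
  SNPs of very large effect the Wald statistics are mildly conservative
  relative to per-SNP REML (the exact mode exists for cross-checking).
* No LD-weighted, MAF-stratified, or dominance GRMs; no product-kernel
  (A o ee') GxE variant — the stratified-group kernel is the implemented
  convention.
* Sample-level QC beyond call rate, imputation, and sex-chromosome handling
  are out of scope.
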