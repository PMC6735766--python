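# Methods

`clinescan` implements a gene-based local-adaptation analysis for a species
sampled along two environmental transects (latitudinal and altitudinal) and
phenotyped as clonally replicated trees in common gardens.  This note
documents the statistical models, the synthetic-data generator that stands in
for the unavailable field data, the numerical choices, and the limits of what
the validation experiments demonstrate.

## Phenotype model: clone BLUPs

Each trait in each garden follows a crossed random-effects model

    y_ijk = mu + b_i + c_j + e_ijk,

with block effects `b_i ~ N(0, s2_block)`, clone effects `c_j ~ N(0,
s2_clone)` and residuals `e_ijk ~ N(0, s2_e)`.  Variance components are
estimated by REML: the residual variance is profiled out and the two variance
ratios are optimized on the log scale with L-BFGS-B (start at ratios = 1,
`ftol` 1e-10, bounds e^±12).  The likelihood is evaluated in the
random-effect dimension via the Woodbury identity, so a 200-clone fit costs a
~204-dimensional Cholesky per iteration rather than anything in the number
of observations.  Empirical BLUPs of the clone effects — shrinkage estimates
whose variance never exceeds that of raw clone means — are the phenotypes for
all association scans.  On balanced designs the estimates coincide with the
ANOVA method-of-moments components (tested), and they agree with
statsmodels' MixedLM crossed-variance-component fit (tested).

## Association scans

**GLM.**  Per SNP, OLS of the BLUP phenotype on the 0/1/2 dosage plus an
intercept and optional PC covariates.  The reported effect is the dosage
coefficient; the reported `r2` is the squared partial correlation between
dosage and phenotype given covariates, i.e. the square of the correlation of
the two residualized vectors, with a two-sided t test on n − p − 1 degrees
of freedom.  The whole scan is a pair of matrix products after one QR of the
covariate block.

**MLM.**  A single polygenic random effect with covariance `s2_g K` is added,
where K is the centred genomic relationship matrix `W W' / Σ_m var(d_m)`
(dosages centred at twice the allele frequency; the normalizer is the summed
observed dosage variance, which equals `2 Σ p(1−p)` in expectation under
Hardy–Weinberg and makes the average diagonal 1).  The model is solved
EMMAX-style: one spectral decomposition of K, a 1-D bounded REML search for
the variance ratio on the covariate-only model, then per-SNP weighted least
squares with the ratio held fixed across SNPs.  This is an approximation to
per-SNP REML; it is standard, orders of magnitude faster, and exact when the
SNP effect is small.  With K = I the scan reproduces the GLM (tested to
1e-6).

**Model choice.**  Candidate models are `simple`, `PC2`, `PC5`, `PC10`, `K`
and `PC2+K`.  Each is scored by the genomic inflation factor
`lambda_GC = median(chi2_1-quantile(p)) / 0.4549364`, and the most
parsimonious model with lambda in [0.98, 1.22] is selected (fallback: the
model nearest the window, with a warning).

**Climate scans.**  Genotype–environment association is a Spearman rank
correlation between dosage and the provenance climate value propagated to
its clones (midranks for ties), reported as rho² with the asymptotic
two-sided t approximation.  rho² plays exactly the role the GWAS r² plays in
the gene-based machinery below.

**Discovery vs corrected scans.**  In the synthetic studies every causal
locus is clinal by construction, so its signal is collinear with population
structure and a PC/kinship-corrected scan removes most of it along with the
confounding.  The gene-based test consumes within-scan *ranks*
(first-percentile outliers), which are invariant to the uniform inflation an
uncorrected scan carries; the analysis therefore uses the plain GLM as the
discovery scan for candidate ranking and reports the lambda-selected
corrected scan alongside it for per-SNP inference.  The structure-correction
machinery is validated separately on null studies where the phenotype is
confounded with provenance but no SNP is causal.

## Gene-based top-candidate test

SNPs are assigned to the gene containing them or within 2 kb (nearest gene
boundary on overlapping flanks, ties to the lower start coordinate); SNPs
outside every gene neighbourhood go to 5-kb windows tiled from the start of
each maximal gene-free interval.  For one scan, the `ceil(0.01 M)` smallest
p-values are outliers (ties by p then SNP id).  The expected per-gene outlier
proportion p̄ is the mean of `n_outliers / n_snps` over bins with ≥ 5 SNPs
and ≥ 1 outlier, and a bin is a top candidate when its outlier count
*strictly exceeds* the 0.999 quantile of Binomial(n_snps, p̄).  Gene-wise
p-values are the binomial upper tail, 1 for bins without outliers.

The ≥ 1-outlier conditioning makes p̄ deliberately conservative: under pure
1% noise flags on realistic bin-size distributions p̄ is ~0.04, four times
the nominal rate, because small eligible bins contribute proportions like
1/5.  The calibration experiment measures both consequences: the fraction of
false candidate bins is ~2e-5 (far below 5e-3), and a gene planted with 5
outlier SNPs is only recovered when its SNP count is modest (overall
sensitivity ~0.4 at geometric mean size 30).  The test trades sensitivity
for a very low false-candidate rate; it detects *concentrations* of signal,
and genes where a fixed number of outliers is diluted among many SNPs are
missed by design.

## Null-W test of parallel adaptation

For each top-candidate gene from transect A, the gene's SNP scores (r² or
rho²) *in transect B* are compared against a control panel of up to 10,000
SNPs sampled (seeded, without replacement) from B's non-candidate bins.  The
comparison is a two-sample rank-sum statistic
`W = #{(control, gene): gene > control} + ties/2`, standardized as

    Z = (2W − n1 n2) / sqrt(n1 n2 (n1 + n2 + 1) / 3),

with n1 the panel size and n2 the gene's SNP count.  An empirical null is
built by computing the same Z for every non-candidate bin of B; each bin's
own SNPs are excluded from the panel side of its test to avoid
self-comparison.  The empirical p of a candidate is the fraction of null Z
values strictly exceeding its Z, floored at 1/N_null, BH-adjusted across
candidates; q ≤ 0.05 declares a parallel outlier.  The per-bin rank-sum is
computed against a pre-sorted panel by binary search (algebraically identical
to full re-ranking; tested against an all-pairs oracle).

Direct overlap between the two transects' candidate sets is scored by the
upper-tail hypergeometric test with the number of bins as the universe.

## Redundancy analysis

Climate predictors are z-scored after a greedy collinearity walk (keep a
variable iff max |r| with the kept set < 0.75, in the given priority order).
RDA centres the dosage matrix Y, regresses it on the predictor matrix X, and
takes the SVD of the fitted values scaled by sqrt(n−1): squared singular
values are the constrained eigenvalues, left vectors × singular values the
sample scores, and unit-norm right singular vectors the locus scores (sign
fixed so each axis's largest-magnitude loading is positive; the outlier rule
below is scale- and sign-invariant per axis).  On each of the first three
axes, SNPs with |locus score − mean| > 3 SD are outliers, each attributed to
the predictor with the largest |Pearson r| against its dosage.

## The synthetic-data generator

The generator produces the full study the pipeline expects, with known truth:

* **Design.**  68 latitudinal provenances × 4 clones and 13 altitudinal
  provenances × 13 clones (441 clones, matching the published design's
  285/166 split in shape), each clone with 4 ramets, one per block, in each
  of 2 gardens.
* **Genome.**  2,000 genes of 2–5 kb on 19 chromosomes with 6–20 kb gaps,
  ~18 SNPs per gene (Poisson, min 1) plus 4,000 intergenic SNPs placed > 2 kb
  from any gene — ~40k SNPs.
* **Neutral structure.**  Balding–Nichols with a common F (default 0.15):
  ancestral `p0 ~ U(0.05, 0.95)`, provenance frequency
  `~ Beta(p0(1−F)/F, (1−p0)(1−F)/F)`, genotypes Binomial(2, p).
* **Causal architecture.**  Causal genes (default 20 per transect, 10
  shared) have *all* their SNPs follow a linear frequency cline in the
  transect's gradient (slope 0.35 × U(0.6, 1), one coherent direction per
  gene) — emulating LD between a selected variant and the SNPs of its gene,
  the feature the gene-based test exploits.  Five SNPs per causal gene carry
  trait effects (half-normal, sd 0.3) whose sign is aligned with the cline,
  emulating directional selection: the locally adapted trait is clinal, as
  the motivating traits (bud phenology, height, cold injury) are.  Shared
  genes are clinal with the same orientation and effects in both transects.
* **Phenotype.**  Clone value = Σ dosage × effect + an environmental
  provenance term (0.5 × gradient position); observations add a grand mean,
  block effects and residual noise scaled so clone-level repeatability
  matches `h2_clone` (default 0.6).  Gardens share clone values and differ
  in block/residual draws.
* **Climate.**  21 named variables, each an affine function of the transect
  gradient (loading ±U(0.6, 1)) plus independent noise (sd 0.3) — the
  correlation structure the scans rely on, with no claim to climatological
  realism.

What the generator does **not** emulate: within-gene LD beyond the shared
cline (neutral SNPs in a gene are independent), linkage between genes,
non-clinal selection, phenotypic plasticity differences between gardens,
missing-data patterns of real exome capture (a uniform missingness rate is
available but defaults to 0), and any real climate surface.  Passing tests
therefore demonstrate that the *statistical machinery* behaves as designed
under the assumed generating model — calibration under the null, power and
FDR control under planted truth — not that the pipeline would reach the same
numerical results on the original field data.

## Validation experiments and problem sizes

* **Overlap tests**: recomputed exactly from the published candidate counts
  (universe 42,970 bins); pure function of printed inputs.
* **Null-W recovery**: 20 full two-transect studies (~40k SNPs, 441 clones)
  with 10 shared + 10 specific causal genes per transect; plus 10 studies
  with zero shared genes for the FDR bound.  ~9 s each.
* **Top-candidate calibration**: 42,970 bins, geometric sizes (mean 30),
  ~1.29M SNPs, exact 1% flags; 100 planted genes.
* **Structure correction**: 20 null studies (20 provenances × 15 clones,
  ~6.5k SNPs) with a provenance-confounded phenotype; all six structure
  models fitted and lambda-selected.
* **BLUP recovery**: 200 clones × 4 blocks, s2_clone = s2_e = 1.

## Numerical conventions and edge cases

Coordinates are 1-based inclusive throughout (VCF and GFF3 agree); strand is
ignored for flanks.  Missing dosages are mean-filled after filtering
(missingness < 0.25, MAF > 0.05, both strict).  Half-called genotypes are
treated as missing entries; non-biallelic records are dropped; both are
counted and logged.  LD pruning scans in seeded random order and compares
each SNP to the last 100 kept SNPs of its chromosome.  PCA components and RDA
axes fix signs by the largest-magnitude loading.  The chi-squared(1) median
uses scipy's exact value, so p = 0.5 maps to lambda = 1 identically.
Empirical null-W p-values are floored at 1/N_null before BH.  Monomorphic
SNPs are skipped in kinship; an all-monomorphic table is an error.  A scan
with no eligible bins (no bin with ≥ 5 SNPs and an outlier) raises a
dedicated error rather than silently substituting a rate.

## Known limitations

The binomial top-candidate expectation is upward-biased by construction (see
above), so candidate counts are conservative and sensitivity for
weak-concentration genes is limited.  The EMMAX approximation slightly
misstates per-SNP variance ratios when single-SNP effects are large.  The
null-W empirical p is discrete in 1/N_null steps, which makes BH adjustment
conservative near the floor.  Bin assignment takes the annotation at face
value; overlapping gene flanks are resolved by distance, not biology.
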