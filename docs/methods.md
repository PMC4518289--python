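# Methods

This note records the statistical models heritkit implements, the defaults
it ships, the numerical choices behind the fits, and what the synthetic
data generator does and does not emulate.

## The GRM mixed model and REML

The core estimand is SNP heritability: the proportion of phenotypic
variance captured jointly by the additive effects of genotyped common
variants.  For phenotype vector `y` (n subjects), fixed effects `X` and one
or more genetic relationship matrices `G_c`, the model is

    y = X b + sum_c g_c + e,
    V = Var(y) = sum_c G_c sigma2_c + I sigma2_e,

and `h2_c = sigma2_c / (sum_c sigma2_c + sigma2_e)`.  Each `G_c` is the
standard allele-frequency-standardized GRM over the SNPs of annotation
category `c`:

    A_jk = (1 / M_jk) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with the inbreeding-adjusted diagonal
`A_jj = 1 + (1/M_j) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i))`,
in-sample allele frequencies, and per-pair SNP counts under missingness.
The adjusted diagonal matches the GRM files the wider GCTA ecosystem
exchanges; note that with in-sample frequencies the rows are approximately
centred, so the mean off-diagonal among unrelated subjects sits at
`-1/(n-1)` rather than exactly 0 — relevant when interpreting small-cohort
GRMs and planted-kinship simulations.

Variance components are estimated by restricted maximum likelihood.  The
restricted log-likelihood is used in the convention

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],

dropping the data-independent constant; the error-contrast formulation
`-1/2 [log|K'VK| + y'K (K'VK)^-1 K'y]` differs by the fixed `-1/2 log|X'X|`
and is used as an independent oracle in the tests.

### Optimization

`reml_fit` runs average-information (AI) REML:

* two EM-REML warm-up iterations for stability, then AI (expected/observed
  information average) Newton steps;
* step-halving on the AI direction (up to 12 halvings) whenever a full step
  would reduce the likelihood or leave the feasible region — without this
  the two-component fits can crawl below their own nested submodels on
  near-null data;
* nonnegativity by projection onto a floor of `1e-6 * var(y)` (the
  customary constraint scale); a component pinned at the floor for three
  consecutive iterations is fixed there, and the final likelihood is
  re-evaluated with floored components at exactly 0 so a boundary fit never
  scores below its nested submodel;
* convergence when the log-likelihood changes by less than `tol = 1e-8`;
  non-convergence is flagged on the result, never raised;
* initialization `sigma2_c = var(y) / (2 C)`, `sigma2_e = var(y) / 2` —
  deterministic and seedless;
* standard errors from the inverse AI matrix at the optimum; proportions
  (`h2_c`) and their SEs by the delta method.

For a single genetic component the fit runs in the eigenbasis of `G`
(`V` diagonal after rotation), making each iteration O(n p^2) after one
eigendecomposition; the dense multi-component path and the eigen path are
cross-checked against each other in the tests.

### Likelihood-ratio tests

Dropping one genetic variance component puts the parameter on the boundary
of its space, so the null distribution of `2 (logL_full - logL_reduced)` is
the mixture `1/2 chi2_0 + 1/2 chi2_1` (a statistic of exactly 0 has
p = 0.5).  A plain `chi2_1` null is available by flag.  Dropping q > 1
components uses a conservative `chi2_q` with a warning — the correct
mixture weights depend on the AI matrix geometry and are not implemented.
With 12 phenotypes the Bonferroni threshold 0.05/12 = 0.004 (two
significant figures) is reported next to raw p-values.

## Annotation partitioning

* **Genic annotation.**  Gene spans arrive as BED (0-based half-open) and
  become 1-based closed internally; a SNP is genic iff it lies within
  `[gene_start - flank, gene_end + flank]` with `flank = 20 kb` by default.
  Gene boundaries are treated as UTR-to-UTR spans; the flank applies to the
  span, and finer exon/intron/UTR subcategories are representable as
  multi-way partitions but not first-class.
* **LD-weighted scores.**  Per-SNP conservation (phastCons-style) scores
  are smoothed by the pairwise LD matrix so tagging SNPs inherit their
  partners' annotation.  The weighting is the self-inclusive r^2-weighted
  average `s~_i = sum_j r2_ij s_j / sum_j r2_ij` over scored SNPs within a
  1 Mb window (`r2_ii = 1`): this keeps weighted scores on the raw scale —
  a convex combination, so a constant vector is invariant — where the bare
  matrix-vector product (available via `normalize=False`) would not be.
  The window and normalization are package choices; r^2 (not signed r) is
  used throughout.  SNPs with no score and no scored LD partner keep a
  missing weighted score and are excluded from partitioning, mirroring how
  unscored SNPs are dropped in practice.
* **Median split.**  Weighted scores above the median are `high`, at or
  below it `low`; with continuous scores the split is balanced to within
  one SNP.  An all-constant score vector is a degenerate split and raises.

## Quality control and relatedness

One QC pass applies, in a fixed order: sample missingness > 5% (strict),
SNP MAF < 1%, SNP Hardy–Weinberg 1-df chi-square P < 1e-6, sample
heterozygosity-rate outliers beyond 5 SD.  The chi-square (rather than an
exact test) is deterministic and matches classical toolchain behaviour at
common allele frequencies; it is the documented swap point.  Because the
heterozygosity pass changes the sample set the SNP filters saw, one pass is
not idempotent in general; `qc_filter_fixpoint` iterates (at most 5 passes
on the data classes tested).  MAF uses mean dosage / 2 and so tolerates
fractional imputed dosages; HWE and heterozygosity use hard calls only.
An optional per-SNP imputation-quality column filter (r^2 > 0.5) stands in
for upstream imputation QC.

Cryptic relatedness is pruned greedily on the GRM: while any off-diagonal
entry exceeds the threshold (0.025 strict or 0.1 relaxed), the subject in
the most above-threshold pairs is removed, ties broken toward the later
subject in input order.  Greedy max-degree removal is deterministic and,
on the small instances where exhaustion is feasible, within one subject of
the maximum retained set; both thresholds can be run side by side as a
robustness check.  The top 10 eigenvectors of the (pruned) GRM enter the
REML fixed effects as ancestry covariates; PCA is on the GRM itself, not
an allele-sharing distance matrix.

## Twin ACE model

Twin phenotypes are modelled as exchangeable bivariate normal per pair with
common variance and correlations `rMZ = a2 + c2`, `rDZ = a2/2 + c2`
(standardized additive-genetic, shared- and unique-environment components).
`fit_ace` maximizes this likelihood directly rather than through a
path-model engine — the estimand is identical and the closed-form
correlation structure is easy to verify.  The optimization is parameterized
in `(mean, log variance, rMZ, rDZ)`, where the likelihood factorizes over
zygosity and the ACE constraints become the wedge
`rMZ/2 <= rDZ <= rMZ <= 1`; this matters because in the `(a2, c2, e2)`
parameterization the likelihood is flat in the a/c split as `e2 -> 0` and
quasi-Newton optimizers stall on that ridge.  Nested AE/CE/E submodels are
fitted the same way and compared by likelihood ratio; Falconer moment
estimates (`a2 = 2(rMZ - rDZ)`, `c2 = 2 rDZ - rMZ`, `e2 = 1 - rMZ`) are
provided untruncated.  Intraclass correlations use the double-entry
(pair-symmetrized) Pearson estimator, which is deterministic and invariant
to within-pair ordering; the one-way ANOVA ICC is available by flag.
Wald confidence intervals come from a finite-difference Hessian; the ML
a2 estimator carries a small (~0.01) downward bias at realistic sizes when
the true shared-environment component sits near its boundary.

## Phenotype preparation

Vertex-level surface areas are collapsed to regions by fuzzy-parcellation
weights (weighted *average* by default — `sum_v w_vr area_v / sum_v w_vr` —
with a weighted-sum variant, which interacts differently with the global
normalization).  Each regional value is divided by the subject's total
surface area so that downstream genetic effects are region-specific.
Residualization regresses on: an intercept; a natural cubic spline basis of
age with 4 degrees of freedom (knots at quantiles; the basis nests linear,
and 4 df absorbs the curvature of lifespan age trends across a 3–90 year
range — configurable); sex; the age-spline-by-sex interaction; and
treatment-coded scanner, diagnosis and cohort factors.  The spline is the
standard truncated-power natural-spline construction (boundary-linear),
built in-package because general formula machinery either aliases its
spline basis with the intercept or is not needed at this design size.
Rank-deficient designs raise and name the aliased columns.  Residualize-
then-model is the default pathway; covariates can instead enter the REML
fixed effects directly, and both routes are exercised in the tests.

## The synthetic cohort

`SimulationConfig` defines the study conditions all statistical checks run
under; its defaults are the conditions, not tuning knobs.

* **Genotypes.**  Two haplotypes per subject; per-SNP allele frequencies
  uniform on [0.05, 0.5] (common SNPs); LD blocks of 20 SNPs at 1 kb
  spacing on one synthetic chromosome; within a block, haplotype alleles
  follow a margin-preserving first-order Markov chain with target lag-1
  correlation 0.5.  For a binary chain the attainable correlation between
  adjacent SNPs is bounded by their frequencies, so the target is clipped
  per pair; with a wide MAF range the realized mean correlation falls below
  the target, and exact-correlation checks use narrow MAF ranges where the
  target is feasible.  This is deliberately not a coalescent: blockwise
  Markov LD is sufficient to exercise LD weighting and GRM estimation and
  is trivially verifiable.
* **Annotation.**  Non-overlapping synthetic genes cover ~50% of the span;
  conservation scores are Beta-distributed with mean elevated inside genes
  (0.60 vs 0.30, concentration 8) and block-level jitter for spatial
  autocorrelation; 2% of SNPs carry no score, because unscored SNPs and
  their elimination are part of the analysis being tested.
* **Phenotype.**  `y = sum_c Z_c beta_c + f(age) + 0.5 s * sex + cohort
  shifts + e` on standardized genotypes with `beta ~ N(0, h2_c / m_c)` over
  a 5% causal fraction per category; defaults h2 = 0.45 total, split
  0.30 genic / 0.15 intergenic.  The age effect is quadratic — nonlinear on
  purpose, so linear-only adjustment demonstrably fails.  Realized genetic
  values are rescaled so the realized heritability equals the target
  exactly (each category to its own target, then jointly to the total — a
  per-category ratio is therefore exact, while individual categories can
  shift by the small joint correction).  This sharpens parameter-recovery
  tests; `rescale_exact=False` restores the random-realization behaviour.
* **Relatedness.**  Planted pairs share one haplotype on a fraction
  `2 * kinship` of LD blocks (both haplotypes on `2k - 1` when k > 0.5),
  giving expected GRM entries equal to the target kinship, up to the
  `-1/(n-1)` centering term above.
* **Twins.**  Exchangeable bivariate normal pairs at the correlations the
  ACE truth implies; defaults 134 MZ + 99 DZ pairs with truth
  (0.60, 0.02, 0.38), i.e. population correlations 0.62 / 0.32.

What the generator does **not** emulate: coalescent/demographic structure,
allele-frequency spectra, X-chromosome or sex-specific genetics,
imputation-dosage uncertainty, genotyping batch effects beyond a cohort
label, assortative mating, or non-additive (dominance/epistatic) variance.
Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions and robustness of the pipeline plumbing — not
robustness to the many ways real cohort data violate those assumptions.

## Problem sizes and reproducibility

The statistical acceptance checks run at: n=2000 / M=8000, 20 seeds
(single-GRM recovery of h2 = 0.45); n=1000 / M=4000, 20 seeds
(two-component partition at truths 0.30/0.10); n=500 / M=1000, 200 null
replicates (LRT calibration); 134 MZ + 99 DZ pairs, 50 replicates (ACE).
These sizes give Monte-Carlo error comfortably inside the stated acceptance
bands while keeping a full run in minutes on one core.  All simulators
draw from `numpy.random.Generator` streams derived from a single seed with
fixed per-operation salts, so identical seeds give byte-identical outputs
regardless of call order; the pipeline additionally hashes its outputs into
a provenance log.

## Known limitations

* Multi-component AI-REML is dense (O(n^3) per iteration) and intended for
  cohorts up to a few thousand subjects.
* The q > 1 likelihood-ratio null is conservative (plain chi-square), and
  SEs for components fixed at the zero boundary are Wald approximations of
  limited meaning.
* Bivariate (genetic-correlation) REML, GWAS association, sex-limitation
  and ADE twin models, phasing and imputation are out of scope.
* `prune_related` is greedy; the exact maximum unrelated set is NP-hard in
  general, and the greedy set can be one short of optimal on adversarial
  graphs.
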