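# Methods

This note documents the statistical models, the synthetic-cohort generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Mixed model and heritability

Every model fits, for one trait at a time,

    y = Xb + Zu + e,   u ~ N(0, G σg²),   e ~ N(0, I σe²)

with an intercept as the only default fixed effect (arbitrary covariate
columns can be supplied). Narrow-sense heritability is h² = σg²/(σg²+σe²);
`ModelFit` recomputes h² from its stored components in the constructor so
the identity holds exactly in every report.

### GBLUP (REML)

`G` is the VanRaden (method 1) genomic relationship matrix:
`Z = M − 2p` column-centers the dosage matrix by the observed
alternate-allele frequencies of the panel itself, and
`G = ZZᵀ / (2 Σ pⱼ(1−pⱼ))`. Monomorphic SNPs are rejected (the denominator
share is zero and the column cannot be centered) unless an internal lenient
flag is set, used only when subsetting individuals during cross-validation
re-fixes a few alleles.

REML profiles the restricted likelihood down to the single variance ratio
λ = σg²/σe² using the eigendecomposition G = UDUᵀ: for fixed λ the
covariance is σe²·U(λD+I)Uᵀ, fixed effects come from weighted least squares
in the rotated basis, and σe² is profiled analytically. The scalar search
runs bounded Brent minimization over log λ on [1e−6, 1e6] with tolerance
1e−8; an optimum within ~0.1% of either bound sets a `boundary` flag (the
fit is still returned). A unit test checks the optimum against a brute-force
grid of the same criterion at 1e−3 spacing.

Breeding values are the BLUP conditional means
`u = λG(λG+I)⁻¹(y − Xb̂)`; out-of-sample prediction uses the train/test
blocks of a joint GRM, `u_test = λ G_ts,tr (λG_tr + I)⁻¹ (y_tr − X_tr b̂)`.

### Bayesian alphabet (single-site Gibbs)

BayesRR, BayesA, BayesB, BayesC and BayesL share one numba-compiled
single-site Gibbs kernel over the intercept/covariates, the m marker
effects, and the variance parameters; the residual vector is updated
incrementally so a marker update costs two length-n dot products. The
marker matrix is centered by the training panel's allele frequencies — the
same centering the GRM uses — so GEBVs are directly comparable with GBLUP
and new individuals are centered by the *training* frequencies.

Priors, with df₀ = 5 throughout (`prior_df`):

- residual: σe² ~ scaled-inv-χ²(df₀, S_e), S_e chosen so the prior mode is
  half the phenotypic variance;
- BayesRR / BayesC slab: one common marker variance, scaled-inv-χ² with the
  mode set so the implied genomic variance (variance × Σⱼ var(zⱼ), divided
  by 1−π for the spike models) is the other half of var(y);
- BayesA / BayesB slab: per-marker scaled-inv-χ² variances with the same
  mode rule. For BayesA the scale S additionally carries a
  Gamma(1.1, rate) hyperprior with prior mode at the initial S, updated by
  its conjugate conditional each sweep. Without this adaptive scale the
  heavy-tailed all-markers-in model badly inflates the genomic variance
  (h² ≈ 0.68 on a cohort simulated at 0.4); with it BayesA tracks GBLUP.
  For BayesB the adaptive scale couples poorly with the fixed-π spike
  (posterior-mean h² drifted with chain length), so BayesB keeps the fixed
  scale — both behaviours were measured on the n=400/m=1000 fixture.
- spike models: π = 0.95 is fixed (the study's setting), i.e. a marker has
  prior probability 0.05 of a non-null effect. Inclusion is sampled from the
  marginal likelihood ratio with the effect integrated out.
- BayesL: Park–Casella parameterization, αⱼ ~ N(0, σe²τⱼ²),
  1/τⱼ² | rest ~ inverse-Gaussian, and λ² ~ Gamma(1.1, rate) with the prior
  mode again implying the half-variance genomic share.

Chain defaults are the study-faithful 50,000 iterations / 5,000 burn-in /
thinning 5; `GibbsSettings.desk()` (6,000 / 1,000 / 5) is the preset used in
tests and examples. Chains are exactly reproducible given `seed`.

**Genomic variance.** Reported Vg for the Bayesian models is the posterior
mean of var(Zα) across individuals, evaluated per stored draw (it falls out
of the maintained residual for free). This matches GBLUP's σg² scale and is
robust to linkage disequilibrium among markers, unlike summing marker
variance parameters.

## GWAS

The association scan is EMMAX-style: the variance ratio is estimated once
by REML under the no-SNP null and held fixed; each SNP is then tested by
generalized least squares in the eigenbasis of G, with the Wald statistic
(β/se)² referred to χ²(1). An `exact_ratio` switch re-optimizes the ratio
per SNP. SNPs with zero variance after rotation get p = 1 and a flag.
λ_GC is median(χ²) divided by the exact χ²(1) median (0.45494).
Thresholds: Bonferroni α/n_tests and the suggestive 10⁻⁴ (−log₁₀ p > 4).
Per-SNP variance explained uses the standard 2p(1−p)β²/var(y), clipped to
[0, 1]. Candidate windows are ±100 kb around a hit, clipped to [1,
chromosome length], reporting any gene whose span overlaps the window by at
least 1 bp (1-based inclusive coordinates throughout). Structure PCA is the
SVD of the column-standardized dosage matrix and is reported descriptively;
the LMM relies on G for structure by default, with PCs available as
covariates.

## Cross-validation and marker density

`make_folds` draws, per repeat, a uniform random permutation split into k
near-equal folds (fold sizes differ by ≤ 1; with 455 individuals and k = 5,
training sets are 364 and test folds 91). Repeat r is seeded as
base_seed + r. The same plan object is shared by all models so every model
sees identical train/test splits. Predictability is the Pearson correlation
between predicted GEBVs and raw observed phenotypes in the test fold; an
optional accuracy column divides by √ĥ². Fitting routines receive only the
training slice of the phenotype vector, so test phenotypes cannot leak;
test *genotypes* may enter the GRM and marker centering, as is standard.

The density experiment refits GBLUP on SNP subsets of increasing size under
three cumulative strategies: `gwas_ranked` (ascending p; ties broken by
genome order), `random` (seeded permutation prefix, hence nested), and
`evenly_spaced` (genome-order indices ⌊j(m−1)/(size−1)⌋, deduplicated and
padded from the nearest unused indices). GWAS ranking is recomputed within
each training set by default; `rank_on_full_data=True` reproduces a single
global ranking, which leaks test phenotypes into selection and is off by
default. The default reporting grid is 50, 100, 200, 300, 500, 800, 1 K,
2 K, 3 K, 5 K, 8 K, 10 K, 13 K and the full panel, truncated to the panel
size.

## Synthetic cohort generator

The generator emulates the statistical shape of a closed aquaculture
breeding cohort: 455 individuals, 16,162 biallelic SNPs on 24
pseudo-chromosomes (2,000 SNPs in most test fixtures), MAF uniform on
[0.05, 0.5], three traits with heritabilities 0.38/0.33/0.24, trait means
130.71 g / 18.12 cm / 7.07 cm and SDs 32.88 g / 1.41 cm / 0.59 cm, genetic
correlations 0.76–0.88 and phenotypic correlations 0.81–0.88. Genotypes are
binomial(2, pⱼ) under Hardy–Weinberg equilibrium and, by default, linkage
equilibrium; an `ld_blocks` mode copies each haplotype's previous-SNP state
with probability `ld_r` to create decaying LD (used by the pruning and
prediction-accuracy tests). QTL effects (default m/4 QTL; any sparser or
denser architecture can be requested) are drawn multivariate normal across
traits with the requested genetic correlation, then rescaled per trait so
the realized genetic variance is exactly h²·var_P; environmental deviations
are multivariate normal with the cross-trait covariance solved against the
realized genetic covariance to approach the phenotypic-correlation target —
an infeasible target (non-PSD implied environmental covariance) raises an
error naming the offending trait pair. The paper-shaped defaults leave the
environmental correlation implied rather than asserted, since only genetic
and phenotypic correlations are specified.

**What the generator does not emulate — and what that implies.** Real
ddRAD cohorts have linked markers and family structure (the study's fish are
offspring of 260 broodstock). Two consequences matter when reading test
results:

1. Absolute predictability is lower here. With unrelated individuals and m
   independent markers, prediction accuracy is roughly
   √(n h²/(n h² + Me)) with Me ≈ m, so a 455-fish cohort at h² ≈ 0.4 and
   m = 2000–4000 predicts at r ≈ 0.1–0.2 rather than the ≈ 0.3 seen with
   real, linked, related data. Ratios (density plateau, model concordance)
   transfer; absolute levels do not.
2. The null sampling SD of REML ĥ² is large. With an unrelated-individuals
   GRM the SE is ≈ √(2 Me)/n ≈ 0.14 at n = 455, m = 2000, and about half
   the null draws hit the Vg = 0 boundary exactly, so P(ĥ² ≤ 0.1 | h² = 0)
   is only ≈ 0.8 per cohort. The sharp null check in the unit suite
   therefore runs on an LD cohort (ld_r = 0.9), where the effective marker
   count is small and the check is well powered; the all-cohorts-near-zero
   expectation simply does not hold for linkage-equilibrium panels of this
   size.

## Quality control

Fixed pipeline order: individual call rate ≥ 0.9 → SNP call rate ≥ 0.9 and
MAF ≥ 0.05 (computed on non-missing calls; boundary values kept — "MAF
below 5%" is read as the exclusion rule) → per-SNP mean-dosage imputation
(preserves allele frequencies; downstream code accepts the real-valued
dosages) → optional tag-SNP pruning. Pruning is a greedy left-to-right scan
within each chromosome dropping any SNP whose dosage r² with a retained SNP
in the trailing window (default 50 SNPs) exceeds the threshold (default
0.8). Mean imputation and r² pruning are deliberate, documented stand-ins
for haplotype-based imputation and tagging: imputation quality and tagger
internals are not what this package studies, and both substitutes are fully
specified and testable. All filters are idempotent and `QcReport` counts
reconcile exactly with the dimension changes.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` / the kernel's
  seeded generator; every public entry point takes an explicit seed, and
  the pipeline derives per-stage seeds from one global seed by fixed
  offsets (kept below 2³¹).
- The stored GRM is never ridged; a 1e−6 diagonal ridge may be applied only
  when solving linear systems during prediction. GRM eigenvalues are
  clipped at zero (tolerance 1e−8) before REML.
- Ties at QC thresholds keep the SNP/individual (≥ semantics everywhere).
- `evenly_spaced` uses floor, not round, in its index rule — the floor rule
  is what yields the documented subset {0, 2, 4, 6, 9} for m = 10, size 5.
- Degenerate inputs fail loudly: zero-variance phenotypes, all-missing
  SNPs, empty panels after filtering, infeasible correlation targets and
  mismatched id sets all raise typed errors.

## Problem sizes used by `scripts/acceptance.py`

Heritability recovery averages 10 cohorts of 455 × 2,000; cross-validated
predictability uses one cohort with a 5-fold × 10-repeat plan; GWAS
calibration uses one 455 × 5,000 polygenic-null cohort; the density section
uses 455 × 4,000 with 5 repeats; the six-model comparison uses 400 × 1,000
with an infinitesimal architecture (every marker causal), 5 repeats and a
reduced chain (3,000 / 600 / 5). These sizes keep a full run to a few minutes on
one core while leaving each reported mean with a Monte-Carlo SE a few times
smaller than the effects of interest; cohort-to-cohort variation (the ±0.1
sampling scatter of single-cohort ĥ²) dominates some entries and is
expected.

## Known limitations

- Single-trait models only; the correlated traits are simulated jointly but
  fitted marginally (no multi-trait REML/Gibbs).
- No dominance or epistasis, no genotype-by-environment terms, no
  single-step (pedigree + genomic) matrices.
- The Gibbs samplers report posterior means and SDs but only basic
  convergence evidence (chain-length robustness tests); no formal
  diagnostics beyond that.
- BayesB/C sample the indicator with π fixed; the option to estimate π is
  not implemented.
- The GWAS is the univariate mixed model only; multi-locus methods are out
  of scope.
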