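# Methods

## The analysis in brief

`genconn` implements a joint analysis of psychiatric-risk SNP dosages and
structural brain connectomes.  The inputs are a subjects × SNPs matrix of
effect-allele counts (SNPs pre-selected for genome-wide-significant
association with phenotypes of interest), per-subject symmetric
region × region matrices of mean fascicle fractional anisotropy (fFA),
covariates (age, sex, scanner site, genetic ancestry factors — GAFs),
behavior variables, and GWAS summary statistics for polygenic scoring.

The core model is canonical correlation analysis (CCA) after confound
adjustment and PCA reduction.  Writing X_g for the dosage block and X_c
for the confound-adjusted connection block, both reduced to K principal
components (U, V), CCA finds weight vectors (a_k, b_k) maximizing
corr(U a_k, V b_k) subject to within-block orthogonality.  Each solution
is a *mode of covariation*: a paired genetic canonical score and
connectomic canonical score per subject with canonical correlation r_k.
*Canonical strengths* are the Pearson correlations between an original
feature (SNP or connection) and its block's canonical score.

Because CCA maximizes correlation, r_1 is large even for independent
blocks; inference therefore rests entirely on a max-statistic
permutation test (below), and effect size is reported as the ratio of
the variance explained by the observed mode to the mean explained under
the permutation null.

## Statistical procedures

**SNP selection.**  Catalog rows with p < 5×10⁻⁸ (strict) enter the
analysis when genotyped; a significant but ungenotyped SNP is replaced
by its genotyped LD proxy with the highest r² strictly above 0.8 (ties
broken by lexicographic SNP id).  A SNP significant for several
phenotypes enters the dosage matrix once; all phenotype annotations are
kept for grouped FDR.

**Confound adjustment.**  Per-connection OLS residuals on
intercept + age + sex + one-hot scanner (reference level dropped) + GAF
columns, computed via an orthonormal basis of the design space, so
residuals are numerically orthogonal (|r| < 1e-8) to every covariate.
The adjustment is idempotent and commutes with feature scaling.

**PCA + CCA.**  Column-centered PCA (features on their native scale by
default; a `standardize` flag z-scores first — the choice matters little
on PC-reduced data and centering-only is the package default).  CCA is
solved by thin-QR + SVD: with U = Q_u R_u, V = Q_v R_v, the singular
values of Q_uᵀQ_v are the canonical correlations.  No ridge term is used
— the PC scores are well-conditioned by construction.  The CCA sign is
arbitrary; modes are oriented so the mean canonical connection strength
is ≤ 0 (high scores ↔ reduced average connectivity), overridable with an
explicit reference vector.

**Mode significance.**  10,000 permutations by default: the subject rows
of one block are shuffled relative to the other (the PCA bases of the
unpermuted data are kept — permutation only breaks subject alignment),
CCA is refit, and the maximum |r| across modes is recorded.  Comparing
every observed r_k against this single max-|r| null controls the
family-wise error across modes.  P-values use the add-one convention
p = (1 + #exceedances)/(B + 1), so the floor is 1/(B+1).  Exceedance
counting includes a 1e-12 tie tolerance so a permutation that reproduces
the observed alignment (e.g. the identity under exhaustive enumeration)
counts as a tie regardless of floating-point summation order.

**Strength inference.**  Canonical strengths are recomputed for mode 1
of every permuted fit; each feature's p-value compares its observed
|strength| against its own permuted null via streaming exceedance
counters (memory O(features), not O(features × B)).  A pooled-null
variant is deliberately not the default.  Benjamini–Hochberg FDR is
applied to all connection strengths together and to genetic strengths
within each phenotype group.

**Variance explained.**  Defined as the mean over features of the
squared feature–score correlation; the same quantity is accumulated per
permutation, and the reported effect size is observed/null-mean.  This
is one concrete operationalization of "variance explained relative to
the null"; it is exact for the trivial cases (all features equal the
score → 1; a single feature with correlation 0.5 → 0.25).

**Polygenic risk scores.**  Clumping + thresholding: optional greedy
clumping by ascending p against a user LD table (default r² = 0.1; with
independent SNPs no clumping is needed), then score_i = Σ β_j · dosage_ij
over SNPs with p ≤ t for every t in the high-resolution grid
{5×10⁻⁸, 5×10⁻⁸ + 5×10⁻⁵, …} up to the base study's optimal threshold.
Missing dosages are imputed as 2 × sample MAF.  Association with the
connectomic canonical score is ΔR² = R²(score ~ PRS + GAFs) − R²(score ~
GAFs); the threshold scan is corrected by permuting the target and
repeating the whole scan (internally the scan maximizes the |partial
correlation|, which is monotone in the model p, and thresholds between
consecutive SNP p-values are deduplicated since they give identical
scores).

**Behaviors.**  Variables need more than ten observations; dichotomous
variables additionally need a minority level of at least 5%.  Adjustment
is OLS on age + sex for continuous variables and logistic response
residuals y − p̂ for dichotomous ones (deviance residuals behind a
switch; perfect separation falls back to linear-probability residuals
with a warning).  One-tailed correlation p-values (H1: r > 0, because
variables are coded so higher = more vulnerable) are combined with
Fisher's T = −2Σ ln p, calibrated by permuting the connectomic score and
recomputing the full p-set — this preserves the dependence among
behavior variables that an analytic χ² combination would ignore.

**Mediation.**  Product-of-coefficients with observed variables: a from
OLS m ~ x, (c′, b) from OLS y ~ x + m, indirect = a·b, Sobel
SE = √(a²SE_b² + b²SE_a²), one-tailed p for indirect > 0.  For
continuous y the decomposition total = c′ + a·b is exact.  The combined
mediation test permutes the *mediator* jointly against (x, y) pairs —
the minimal scheme that breaks both legs of the indirect path while
preserving the x–y relation.

**Robustness.**  Every scenario is an input transformation followed by
the identical pipeline core: random disjoint half-samples; PC counts 50
and 150 against the 100-PC baseline; SNP subsets by phenotype (with a
permutation p from shuffling edge labels); subject exclusion.  Before
comparison the reproduced mode is sign-flipped to maximize its
correlation with the original (CCA signs are arbitrary), and the aligned
correlation is reported.  Network summaries: the per-subject mean
connection strength correlated with the connectomic score (permutation
p), and hubs — per node, the summed significant (q < 0.05) incident
canonical strengths, classed hypo (< 0) / hyper (> 0) / none (no
significant incident edge, or an exact zero sum); a mean-based variant
is available via `average=True` and the choice is recorded in output.

## The synthetic cohort generator

The generator emulates a pediatric imaging-genetics cohort and plants a
single rank-1 mode of known canonical correlation ρ (a single mode
because the analysis targets one dominant mode; a multi-mode option
exists as a config flag).

- **Genotypes.**  MAF ~ Uniform(0.05, 0.5); non-causal dosages are
  independent Binomial(2, MAF).  Causal SNPs are drawn conditional on a
  shared standard-normal factor f: allele probability
  clip(maf_j + loading_j f_i, 0.01, 0.99) with loadings ±0.15.  This
  matters: a fixed linear combination of *independent* SNPs carries no
  excess variance and is destroyed by the PCA reduction the pipeline
  mandates, so no analysis could recover it; the shared factor gives the
  planted genetic direction a leading eigenvalue, the way a real
  polygenic signal rides on correlated allele frequencies.  Causal MAFs
  are drawn from [0.2, 0.5] so the clip rarely binds.  The genetic
  latent g is then *defined* as the standardized weighted sum of the
  realized causal dosages.
- **Connectomes.**  The connectomic latent m mixes g with fresh noise
  orthogonalized against g, so corr(g, m) = ρ exactly in-sample.
  Connection strengths are baseline ~ Uniform(0.2, 0.8) (above the
  fFA 0.2 tractography stopping floor, constant per edge) plus
  effect_j · m_i on the signal edges, plus linear covariate effects
  (coefficients ~ N(0, confound_effect_sd) per edge on standardized
  age/sex/scanner/GAF), plus N(0, noise_sd) measurement noise.  Edge
  effects are drawn 0.03 · N(−1, 0.5), i.e. predominantly negative,
  planting the hypoconnective pattern the sign convention expects.
- **Behaviors.**  y = c′·g + b·m + N(0, 1) for continuous variables;
  dichotomous variables are Bernoulli(logistic(·)) on the same linear
  predictor (prevalence ≈ 0.5, well inside the stable [0.1, 0.9] band).
  Defaults: 8 continuous + 4 dichotomous variables, the first 6 carrying
  (b, c′) = (0.3, 0.2), the rest pure noise; small age/sex slopes
  (SD 0.2) exercise the adjustment step.  Higher values always mean
  higher vulnerability.
- **Summary statistics.**  β̂_j = β_j + N(0, SE_j) with
  SE_j = 1/√(2·MAF(1−MAF)·n_base), n_base = 50,000, true β = ±0.05 on
  causal SNPs and 0 elsewhere; p-values are the two-sided normal tail,
  so non-causal p-values are Uniform(0, 1).
- **LD (off by default).**  Optional block-exchangeable LD for testing
  proxy selection and clumping: SNPs within a block share the block MAF
  and each allele is copied from a block-shared draw with probability
  r²^(1/4), giving pairwise dosage r² equal to the configured value.
- **Seeds.**  One master seed; each sub-generator uses
  `default_rng(SeedSequence((seed, stream_id)))` with fixed stream ids,
  so components are independently reproducible.

Default shape mirrors the cohort the pipeline was designed around
(678 subjects, 1877 SNPs, 120 nodes → 7140 connections); tests and the
acceptance script scale the cohort down (typically 500–600 subjects,
300–500 SNPs, 60 nodes, K = 20 components) so the full battery runs in
minutes on one CPU while keeping every planted effect comfortably
detectable.  With K = 20 the CCA overfitting bias at n = 500 stays small
(null max |r| ≈ 0.35–0.4), so the recovered r₁ tracks ρ closely; at
K = 100 the null itself approaches 0.6–0.7 and recovery must be judged
against the permutation null rather than read off r₁.

What the generator does **not** emulate: realistic LD from reference
panels, population stratification beyond Gaussian GAFs,
Hardy–Weinberg departures, imputation uncertainty, site batch effects
beyond linear scanner shifts, non-Gaussian fFA noise, or
missing-at-random structure in genotypes.  Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under
the stated model, not that real cohort effects of this size would be
detected.

## Numerical choices and degenerate inputs

- Connectome symmetry is validated to 1e-10; the worst entry and subject
  are named on failure.  NaNs anywhere in a block are rejected before
  fitting.
- Zero-variance columns: rejected in CCA input (PC scores never have
  them); excluded with a count from variance-explained; given NaN
  strength/p/q in strength tables.
- Rank-deficient confound designs raise with the collinear columns named
  (pivoted QR).
- p-value floors: permutation p ≥ 1/(B+1) everywhere; zero inputs to the
  combined test are clamped to 1/(B+1) with a warning.
- Hub tie rule: an exactly zero summed strength is classed `none`.
- Text I/O uses `%.17g` floats and round-trip parsing, so every table
  round-trips bit-identically (formats in `docs/formats.md`).

## Known limitations

- The mediator-permutation null for the combined mediation test is
  exactly calibrated under the joint null (mediator unrelated to both
  x and y).  When the x→m path is strong but b = 0, Sobel p-values are
  anticonservative against this null — a known property of
  single-permutation mediation schemes.  Alternative schemes are
  worth considering when the exposure–mediator path is not itself in
  question.
- Strength p-values use per-feature permuted nulls; a pooled null can
  differ when feature variances are heterogeneous.
- The variance-explained estimator is one reading of "variance explained
  vs the null"; other operationalizations (e.g. redundancy indices)
  would scale differently but preserve the observed/null ratio's
  qualitative meaning.
- Half-vs-full robustness correlations share subjects with the full
  sample and are therefore optimistically biased relative to
  disjoint-sample reproducibility; the split-half scenario reports both
  halves so the disjoint comparison can also be formed.
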