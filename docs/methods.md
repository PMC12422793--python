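# Methods

## Data-generating model

The simulator emulates a one-sample MR study of an hourly self-reported
exposure (sleep duration) and continuous aging outcomes in a middle-aged
European-ancestry cohort. For individual *i* with genotype dosages
*g<sub>ij</sub>* ∈ [0, 2] at *m* independent biallelic loci (Hardy-Weinberg,
no linkage disequilibrium — the faithful emulation of an LD-clumped
instrument panel):

```
X*_i = α + Σ_j β_j g_ij + κ_U U_i + ε_xi        ε_xi ~ N(0, σ_x²)
Y_i  = h(X*_i) + δ_U U_i + ε_yi                 ε_yi ~ N(0, σ_y²)
X_i  = round_half_away_from_zero(X*_i)
```

with a single standard-normal confounder *U* shared by exposure and
outcome, and the intercept α solved so that E[X\*] hits the target mean.
The causal dose-response h(x) is configurable: linear (h(x) = βx exactly),
continuous threshold (two slopes meeting at a breakpoint), parabolic
U-shape, or arbitrary continuous piecewise-linear. Records whose observed
exposure is missing, below 2 or above 12 h/d are excluded (bounds kept),
as are incomplete cases; the per-rule exclusion counts are reported.

An optional per-individual lognormal mean-one multiplier on the genetic
effects (`genetic_effect_sd`) produces the gene-exposure effect
heterogeneity that motivates doubly-ranked (rather than residual-based)
stratification; it is off by default. Missingness in the reported exposure
is injected only on request.

### Default parameters and what they emulate

| parameter | default | rationale |
|---|---|---|
| exposure mean / SD | 7.16 h/d, ~1.1 h | marginal distribution of self-reported sleep in a large middle-aged biobank |
| instrument panel | 83 loci, \|β\| ~ U(0.02, 0.06) h/allele, EAF ~ U(0.1, 0.9) | genome-wide-significant sleep loci have effects of ~1–4 min/allele; the panel's aggregate R² ≈ 4% gives first-stage F in the hundreds at n = 10⁴–10⁵, a usable instrument at simulation scale (real panels reach comparable F only at biobank scale) |
| confounder loadings κ_U = δ_U | 0.5, 0.5 | moderate shared confounding; makes the naive regression bias κδ/var(X) ≈ 0.2 outcome-units/h, large enough to separate the observational and IV estimators cleanly |
| outcome residual SD σ_y | 4.0 years | age-acceleration outcomes have total SD ≈ 3–5 years; 4.0 leaves the causal and confounder components a realistic minority share |
| exposure noise σ_x | 0.9 (1.05 when κ_U = 0) | chosen so the *marginal* exposure SD stays ≈ 1.1 h whether or not the confounder path is active — the marginal exposure distribution, not the noise decomposition, is the anchored study condition |

The simulated covariates (age, sex, PCs, array, lifestyle factors) carry
realistic marginals but are independent of exposure and outcome: they
exercise the adjustment machinery without changing any estimand. Passing
tests therefore demonstrate estimator correctness under the stated model,
not robustness to covariate-driven confounding, selection effects,
population structure, LD, or misreporting that depends on the true value —
none of which the generator produces.

## Estimators

**Allele score.** Unweighted count of exposure-increasing alleles:
dosage if the published effect is positive, 2 − dosage if negative;
palindromic variants (A/T, C/G) are excluded because strand orientation is
unresolvable, and a zero effect leaves the increasing allele undefined
(excluded with a warning). Strength is summarised by R² and
F = (n − 2)R²/(1 − R²) from the simple regression of exposure on score.
The variance explained reported here is the share of *phenotypic*
variance; shares quoted against SNP-based heritability are a different
(larger) quantity.

**Observational models.** OLS with Wald 95% CIs and normal quantiles
throughout; complete-case analysis. The restricted cubic spline uses the
truncated-power natural-spline basis with four knots t₁..t₄ and the
(t₄ − t₁)² normalization, so exactly two nonlinear columns accompany the
linear term and the fit is provably linear outside [t₁, t₄]. The
nonlinearity p-value is a joint Wald χ²₂ test of the two nonlinear
coefficients (a likelihood-ratio test is asymptotically identical; Wald
needs one fit). Spline and category contrasts are centred at 7 h/d — the
categorical reference — rather than at the exposure median; the choice is
a reporting convention and does not affect the tests.

**Two-stage IV.** Stage 1 regresses observed exposure on score +
covariates, stage 2 the outcome on the stage-1 fitted values + covariates.
Standard errors use the structural residual y − β̂x<sub>obs</sub> − Zγ̂
(the proper 2SLS variance, not the naive stage-2 OLS one); classical
homoskedastic variance is the default, a sandwich estimator is available
(`robust=True`) — large one-sample GRS analyses rarely state which they
used, and the two agree closely under the generator's homoskedastic noise.
The derived covariates (age², age×sex, age²×sex) are always rebuilt
internally from raw age and sex (age mean-centred before powers, for
conditioning; the exposure coefficient is unaffected).

**Doubly-ranked stratification.** Sort by score into consecutive
pre-strata of 50; within each pre-stratum rank by observed exposure and
deal rank-slices of 10 into the five final strata. Both sorts break ties by
one seeded random permutation — essential for an hourly-coarsened exposure,
where plain stable sorting would leak score order into the strata. A final
incomplete pre-stratum (N mod 50 members) assigns its rank r of s members
to stratum ⌈rK/s⌉, so every participant is labelled and stratum sizes
differ only by the remainder allowance. The construction makes the strata
independent of the score while forcing mean observed exposure to rise
monotonically — both properties are verified by simulation tests.

**Bootstrap averaging and pooling.** Each replicate removes 12
participants at random, restratifies (fresh tie-break) and re-estimates;
per-stratum estimates are pooled with Rubin's rules: pooled mean, total
variance = within + (1 + 1/B)·between. Pooled CIs use normal quantiles
(no small-sample df correction; per-stratum n is large in the intended
regime). With `n_remove=0` every replicate reuses the parent seed — there
is no perturbation to average over, and the pooled result equals the
single-shot one. A replicate whose stratification fails is dropped with a
warning; more than 20% dropped is an error.

**Nonlinearity tests.** Primary: fixed-effect (known-variance) weighted
meta-regression of the stratum LACE estimates on stratum mean exposure,
weights 1/se²; the two-sided normal p-value on the slope tests a constant
causal effect. Secondary: the LACE estimates are treated as observations
of the derivative h′ at the stratum mean exposures and fitted by a
degree-1 fractional polynomial h′(x) = θxᵖ over
p ∈ {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (x⁰ ≡ ln x) by weighted Gaussian
likelihood; the constant-derivative model competes in the same selection,
so homogeneous stratum estimates yield exactly the straight-line curve.
The FP p-value is a likelihood-ratio χ² of the best power model against
the constant model with 2·degree − 1 df (each selected power costs one
df). The reported causal curve integrates the selected derivative
analytically, anchored to 0 at the 7 h/d reference. The optional degree-2
search covers distinct power pairs (repeated-power log terms are omitted).
Both p-values are reported side by side; the trend p is designated primary.

## Numerical choices

- Coarsening rounds halves away from zero (7.5 → 8, −2.5 → −3); hourly
  self-report conventions are not published, so the rule is fixed and
  documented rather than inherited from binary floating-point rounding.
- Rank deficiency is detected by pivoted QR and reported with the names of
  the collinear terms; degenerate first stages (score adding no exposure
  variance beyond covariates) are errors, not silent weak-IV estimates.
- All randomness flows through `numpy` `SeedSequence`-derived generators;
  identical seeds reproduce tables and serialized results bit-for-bit.
- Simulation-based tests use 4-standard-error bands and 100–200 replicate
  designs at n = 10⁴–5×10⁴, sizes at which every check completes in
  minutes on one CPU while keeping Monte-Carlo error well inside the
  asserted bands.

## Known limitations

- Genotypes are independent dosages: no LD, imputation uncertainty, or
  array effects; palindrome handling is exclusion-only (no
  frequency-based strand inference).
- The generator draws age-acceleration outcomes directly; it does not
  simulate the biomarker panels from which such outcomes are derived, nor
  survival/longitudinal structure.
- Exposure misreport is pure rounding; differential misreport and
  selection (healthy-volunteer) effects are absent.
- Only the doubly-ranked stratifier is implemented; the older
  residual-based method is out of scope, as are two-sample
  summary-statistic MR estimators.
- The trend meta-regression is fixed-effect; with few, large strata a
  random-effects variant would differ only when strata are genuinely
  heterogeneous beyond their SEs.
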