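# Methods

## The model

`burdenblend` studies a quantitative biomarker influenced by three genetic
and non-genetic layers at once:

```
y_i = Σ_c γ_c x_ic                     covariates (age, sex, BMI, PC1..PC4)
    + Σ_g β_g · z(GBS_ig)              rare-variant gene burdens, signed
    + Σ_j b_j · d_ij                   additive common-variant polygenic term
    + ε_i,   ε_i ~ N(0, σ²)
```

The gene-based burden score (GBS) of individual *i* at gene *g* aggregates
the gene's qualifying rare variants:

```
GBS_ig = Σ_{v ∈ g} s_v · Beta(MAF_v; 1, 25) · d_iv
```

where `s_v` is a CADD-raw-like deleteriousness score, `d_iv` the
alternate-allele dosage and `Beta(·; 1, 25)` the Beta-density up-weighting
that equals 25 at MAF 0 and decays with frequency — the standard
rare-variant weighting also used by SKAT-family tests. Qualifying means:
functional-consequence flag set, annotation MAF < 0.01, gene assigned,
deleteriousness present. No per-gene normalisation or dosage cap is applied;
negative deleteriousness values are accepted (the simulator emits
non-negative ones). A sample carrying no qualifying allele in a gene scores
exactly 0 there.

The analysis has five stages, each a pure function of (inputs, config,
seed):

1. **Preparation.** Statin users' lipid measurements are divided by a
   published on-treatment factor (cholesterol 0.684, LDL 0.749,
   apolipoprotein B 0.719) to approximate untreated levels. Samples
   without a biomarker value are excluded per trait, then the cohort is
   split 60/30/10 into construction / training / test subsets by a seeded
   permutation, flooring the first two sizes and giving the remainder to
   test — the only rounding rule that maps n = 145,464 onto
   (87,278, 43,639, 14,547).
2. **Scoring.** The GBS matrix above.
3. **Association scan.** For each gene, OLS of the trait on the gene score
   plus intercept and covariates. Effect size z = beta/se; two-sided
   p-values from the exact t distribution with residual degrees of freedom
   (at biobank n this is indistinguishable from the normal approximation;
   at desk n the t is the exact choice under the model). Genes with zero
   score variance are marked untested. Bonferroni correction uses
   m = genes actually tested; "significant" means p < alpha/m. Scan
   calibration is summarised by the genomic inflation factor
   lambda = median(Q_chi2(1-p, 1)) / 0.45494 (the 1-df chi-square median,
   held at full double precision). The scan is computed via the
   Frisch–Waugh–Lovell decomposition — trait and all gene columns are
   residualised on one QR factor of the covariate design, reducing every
   gene to a simple regression — which is algebraically identical to the
   per-gene full OLS (unit tests verify agreement with statsmodels to
   1e-8) but runs the whole scan as a few matrix products.
4. **PRS.** On the construction subset only: the trait is residualised on
   the covariates; SNPs with cohort MAF ≥ 0.01 are ranked by absolute
   marginal correlation with the residual; the top batch (default 500)
   enters an L1 path over 50 log-spaced penalties spanning three decades
   below the null-gradient maximum. The penalty is chosen by R² on a
   held-out 20% validation fold of the construction subset (ties go to the
   larger penalty, i.e. the sparser model); the screen for the validated
   path sees only the fitting fold, since a screen that peeks at the
   validation fold makes screened-in noise SNPs look predictive there. At
   the chosen penalty the model is refit on the whole construction subset
   and the KKT conditions are checked over **all** SNPs; violators are
   batched in and the fit repeated until none remain, so the screened
   solution equals the full-lasso solution at that penalty (verified
   against an unscreened scikit-learn lasso to 1e-6). This preserves the
   batch-screening-iterative-lasso contract at desk scale. Scoring is the
   intercept-free weighted dosage sum; a weights object carries its
   construction sample ids and refuses to score overlapping samples unless
   forced.
5. **Prediction.** Gene predictors = Bonferroni-significant genes on the
   construction subset. Four feature sets: covariates only; covariates +
   selected gene scores; covariates + PRS; all three combined. All features
   are z-scored with training-split statistics (sample n−1 standard
   deviation; zero-variance features are dropped with a log record, never
   divided by). Six regression families — OLS, ridge (alpha 1), lasso
   (alpha 0.01), elastic net (alpha 0.01, l1 0.5), random forest (100
   trees, min leaf 5), gradient boosting (scikit-learn defaults) — are
   scored by mean 10-fold CV R² on the training split; ties resolve to the
   earlier, linear-first zoo order. The winner is refit on the full
   training split and evaluated once on the test split. The headline
   quantity is the incremental R² = test R² minus the covariates-only test
   R², reported as-is (it can be negative). Importances are model-agnostic
   permutation importances on the test split.

Split hygiene is enforced structurally: feature selection and PRS
construction assert their samples lie in the construction subset, training
in the training subset, evaluation in the test subset, and PRS scoring
refuses construction samples; violations raise `LeakageError`.

## The synthetic cohort generator

No individual-level biobank data can ship with the package, so the
generator produces cohorts with the architecture the analysis assumes,
plus full ground truth:

- Rare variants grouped into genes (2–8 per gene), MAF log-uniform on
  [1e-4, 0.009] — heavy at low frequency, always below the 0.01 filter;
  deleteriousness |N(3, 1)| (positive, CADD-raw-like spread; the magnitude
  is arbitrary since only the product with the weight matters).
- Independent common SNPs, MAF uniform on [0.05, 0.5] by default.
- Genotypes Binomial(2, MAF) under Hardy–Weinberg and linkage equilibrium.
- Covariates: age N(55, 8), sex Bernoulli(1/2), BMI N(27, 4), four PCs
  N(0, 1), with small default effects.
- Gene effects apply to the z-standardised true burden, so "standardised
  effect 0.5" means half a trait SD per burden SD for every gene; causal
  SNP effects are N(0, sd) or fixed-magnitude with random sign
  (`snp_effect_dist='fixed'`, the guaranteed-large-effect design used in
  recovery studies).
- Statin users (a configurable prevalence) have their *recorded* trait
  multiplied by the treatment factor; the preparation stage inverts this.
- All randomness comes from `numpy.random.default_rng` (PCG64); a fixed
  seed reproduces cohorts byte-identically across platforms.

What the generator does **not** emulate: linkage disequilibrium, population
stratification beyond the supplied PCs, genotyping error, relatedness,
non-Gaussian trait distributions, and variant-level non-additivity.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to the confounders of
real biobank data.

## Numerical choices

- Missing genotype calls are carried explicitly (−1) and contribute 0 to
  burden scores by default (configurable to per-variant mean dosage, which
  is what PRS scoring uses); they are never silently zero at parse time.
- Beta-density weights at subnormal MAFs are evaluated at 0 (the density is
  continuous there; the underlying incomplete-beta routine overflows on
  subnormals).
- A perfect association fit (zero residual) reports an infinite z and the
  smallest positive double as p, keeping downstream −log10 finite.
- p-values are floored at the smallest positive double; lambda requires
  p ∈ (0, 1].
- Rank deficiency of the covariate design is detected from ~0 diagonal
  entries of its QR factor and reported with the offending column names.
- KKT violation threshold: gradient > alpha·(1+1e-8)+1e-12, with at most
  20 expansion rounds (a warning reports any residual violators).
- Tie-breaks: model families by fixed zoo order; extreme effect-size labels
  by gene symbol order; association table rows sorted by gene then
  position.
- Floats are written with 17 significant digits and parsed with pandas'
  round-trip parser, so every table survives write→read exactly.

## Problem sizes of the bundled studies

The reusable studies in `burdenblend.experiments` (run by the analysis
scripts and the acceptance harness) use: null calibration at n = 5,000
samples × 2,000 genes × 10 seeds; gene sign-recovery with effects ±0.5 at
n = 5,000 × 20 seeds; SNP recovery with 10 of 200 SNPs at fixed magnitude
0.3 and n = 4,000 × 20 seeds; modality comparisons at n = 2,000 (100
genes, 300 SNPs) × 20 seeds per architecture, using the linear
subfamilies of the zoo — linear targets make linear families sufficient
there, and the full zoo is exercised separately in the unit suite. The
demo analysis uses n = 2,000, 200 genes, 500 SNPs.

A note on the null-calibration lambda: with m = 2,000 tested genes the
median-based lambda has standard error ≈ 0.052 even though the p-values
are exactly uniform (Gaussian noise and an exact t-test make them so
conditional on any design). Individual seeds can therefore land outside
[0.9, 1.1] by sampling noise alone (~5% of seeds); the pooled type-I rate
is the stabler calibration summary.

## Known limitations

- The burden-score aggregation form is a reconstruction of a
  frequency-and-annotation-weighted scoring scheme from its published
  description; no per-gene normalisation or dosage cap is applied, and the
  functional filter is a boolean supplied by the annotation table.
- The PRS construction is a desk-scale screened lasso, not a streaming
  biobank solver; covariates are handled by residualisation before
  screening rather than joint unpenalised fitting (configurable in
  principle, fixed here).
- The model zoo is a six-family subset with fixed hyperparameters; no
  tuning loops.
- The direction of the statin adjustment (divide vs multiply) is a
  documented convention, not derivable from first principles here; divide
  restores the pre-treatment scale when factors encode proportional
  on-treatment reduction.
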