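# Methods

## Model

Each trio consists of a mother, father and child genotyped at `n_snps`
independent biallelic variants. Let `S_c`, `S_m`, `S_f` denote true polygenic
scores — centered weighted allele counts `S = Σ_v β_v (G_v − 2 p_v)` with
weights scaled so the population score variance is 1. The latent outcome is

```
y = c·S_c + m·S_m + f·S_f + γ_sex·sex + γ_by·birth_year_z + deme shift + ε
```

where `c` is the **direct genetic effect** and `m`, `f` are the maternal and
paternal **genetic nurture** effects. The analysis fits, per parent:

- *unadjusted*: `y ~ S_parent + covariates`
- *trio*: `y ~ S_c + S_m + S_f + covariates`

Under random mating, `Cov(S_c, S_parent) = 1/2`, so the unadjusted parental
slope estimates `m + c/2` while the trio model estimates `m` directly; the
attenuation `Δβ = β_unadjusted − β_trio` estimates the transmitted component
`c/2`. Under assortative mating with spousal score correlation `a`,
`Cov(S_c, S_parent) = (1+a)/2`, `Var(S_c) = 1 + a/2`, and the unadjusted
slope becomes `m + c(1+a)/2` — these identities are verified numerically in
the test suite.

## What the simulator does

- **Genotypes.** Variant frequencies are drawn uniform on
  `[maf_low, maf_high]`; parental genotypes are binomial (Hardy–Weinberg)
  within each deme. With `n_demes > 1`, per-deme frequencies are
  Balding–Nichols draws, `Beta(p(1−F)/F, (1−p)(1−F)/F)` with
  `F = deme_fst_like`.
- **Transmission.** Each parent transmits per locus: dosage 0 → 0 copies,
  2 → 1 copy, 1 → Bernoulli(1/2). This yields the full segregation law
  (e.g. het × het children are 0/1/2 with probability 1/4, 1/2, 1/4).
- **Assortative mating.** Mothers and fathers are rank-paired on a jittered
  copy of the mating variable (`mate_on ∈ {score, phenotype}`); the jitter SD
  is solved by bisection so the *realized* spousal correlation matches
  `a_target` essentially exactly. This is deterministic given the seed and
  makes targets like `a = 0.2` reproducible, at the cost of not modelling any
  particular behavioural mating mechanism.
- **Effect-size weights.** True weights satisfy `Σ β² · 2p(1−p) = 1`.
  "Observed" GWAS weights add sampling error with
  `SE = 1/sqrt(gwas_n · 2p(1−p))`, so the error variance of a full-panel
  score is approximately `n_snps / gwas_n` — the lever used to study
  imperfect-score behaviour.
- **Phenotype scale.** If `noise_sd` is not given it is solved so the latent
  outcome has population variance 1 (the calculation includes the
  assortment-induced score covariances and the covariate and deme-shift
  variances). The simulated outcome is then z-scored, so `c`, `m`, `f` are
  recoverable as regression coefficients without rescaling.
- **Items and missingness.** The latent outcome is rendered as 18 four-point
  items (latent value plus unit normal per item, cut at 0.5/1.5/2.5 and
  mapped to {1, …, 4}), giving right-skewed responses with totals in
  [18, 72]. Phenotype missingness is
  logistic in the mean of `aux_count` auxiliary variables correlated with the
  outcome (`aux_corr`); `mar_strength = 0` gives MCAR, larger values give
  stronger MAR. The intercept is solved by bisection so the marginal
  missingness rate matches `missing_rate`.

## What it does **not** emulate

No linkage disequilibrium, no dominance or epistasis, no liability-threshold
(binary) outcomes, no sibling or extended-family structure, no
parent-of-origin effects, no genotyping error, and only a two-generation
equilibrium for assortative mating (the parents' own scores are drawn at
unit variance rather than inflated by ancestral assortment). Cross-trait
assortment and environment–genotype correlation beyond the modelled nurture
paths are out of scope.

## Scoring and adjustment

- **Threshold scores.** `score(i, t) = Σ_{p_v ≤ t} β̂_v · dosage(i, v)` after
  aligning counted alleles to effect alleles (dosage → 2 − dosage on flips);
  unmatched variants are dropped with a log message, strand-ambiguous
  (A/T, C/G) variants are flagged.
- **PRS-PC.** Threshold columns are z-scored and the first right singular
  vector gives the composite, sign-aligned with the mean score and
  re-standardized. For two columns with correlation `r` the loadings are
  exactly `(1, 1)/√2` and the leading eigenvalue `1 + r`.
- **Ancestry PCs** are the leading left singular vectors of the
  column-standardized dosage matrix, computed on parents and children stacked
  together so family members share one coordinate system.
- **Residualization** regresses each score on PCs (and any covariates) and
  returns the z-scored residual; categorical covariates are expanded to
  indicators with singleton levels merged.

## Imputation and pooling

Outcome missingness is handled by predictive mean matching: per imputation, a
Bayesian draw of the regression of observed outcomes on the predictors
(σ²* from the scaled inverse-χ², β* from the normal posterior) yields
predicted means, and each missing case copies the *observed* outcome of one
of the 5 donors with closest predicted means (type-1 matching). Pooling uses
Rubin's rules, `T = W̄ + (1 + 1/M)·B`, with the Barnard–Rubin small-sample
degrees of freedom when a complete-data df is supplied.

## Inference conventions

- OLS with HC1 heteroskedasticity-robust standard errors; CIs are
  `β ± 1.96·SE` and p-values use the normal reference.
- The Δβ test refits both models on the identical row set. The default is a
  paired trio bootstrap (`B = 1000`): `p_delta` is the normal-approximation
  p-value from the bootstrap SE (reported as the primary p), a resampling
  p-value with the `(1 + k)/(B + 1)` convention and a percentile CI are also
  recorded. An analytic alternative uses the stacked-sandwich covariance of
  the two estimators and agrees closely with the bootstrap.
- Multiplicity is controlled with Benjamini–Hochberg FDR at `q = 0.05`,
  applied per model family in the pipeline.
- The mechanism classifier combines the adjusted parental coefficient and the
  attenuation test into one of: *genetic transmission*, *genetic nurture*,
  *both*, *inconclusive — possible power limitation*, *no association*.

## Numerical and design choices

- All randomness flows from named substreams of a single `SeedSequence`;
  pipeline stages derive their seeds as `sha256(f"{seed}:{stage}") mod 2³¹`.
  Identical configs give byte-identical outputs.
- Test problem sizes were chosen by analytic power calculations before
  freezing: e.g. the calibration study uses 200 cohorts of 5,000 trios
  (Monte-Carlo SE ≈ 0.0014 per path), and the assortative-mating bias study
  uses `c = 0.3` with score error variance `σ² ≈ 1`
  (`gwas_n = n_snps = 400`) because the nurture bias there is
  `≈ c·σ²·a/4` — exactly zero at `a = 0`, since measurement-error components
  of the score are themselves Mendelian-transmitted and cancel in the trio
  model under random mating.
- Collinearity in the trio design is detected by pairwise score correlation
  (`|r| > 0.9999` names the offending pair); constant scores and
  insufficient sample sizes raise errors rather than warnings.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| `maf_low`, `maf_high` | 0.05, 0.5 | common variants, stable HWE sampling |
| `c`, `m`, `f` | 0.15, 0.05, 0.0 | small direct effect, smaller maternal nurture — the regime where the design is interesting |
| `a_target` | 0.0 | random mating unless studying assortment |
| `gwas_n` | ∞ (perfect weights) | noise is opt-in so analytic identities hold by default |
| `noise_sd` | auto | unit latent variance (see above) |
| thresholds | 5e-8 … 1.0 (9 values) | conventional p-value grid |
| `imputation_m` | 5 | standard minimum for stable pooled SEs |
| donor pool | 5 | conventional PMM choice |
| `dbeta_b` | 1000 | bootstrap SE stable to ~2% |
| `fdr_q` | 0.05 | conventional |

## Limitations

The simulator is a verification instrument, not a population-genetic model of
record: absence of LD means threshold scores differ across thresholds only
through weight noise; the equilibrium effects of sustained assortative mating
on parental score variance are not modelled; the item generator is a
convenience mapping rather than a psychometric model; and all phenotypes are
continuous and Gaussian. Conclusions about real cohorts require the usual
caveats about score portability and residual stratification.
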