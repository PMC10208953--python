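# trionurture

Separating **genetic transmission** from **genetic nurture** with polygenic
scores in mother–father–child trios.

## The scientific problem

A child's polygenic score predicts their traits, but so do the *parents'*
polygenic scores — and for two very different reasons. A parental score can be
associated with the child's outcome because half of the parent's alleles were
transmitted to the child (**genetic transmission**), or because the parent's
genotype shapes the environment the child grows up in (**genetic nurture**,
e.g. via parenting behaviour influenced by the parent's own traits). Ordinary
population analyses cannot tell these apart.

The trio design can. Regressing the child's outcome on the child's, mother's
and father's polygenic scores *jointly* blocks the transmission pathway: the
child's own score is held fixed, so any remaining parental association must
act through the environment. The package implements this design end to end:

- **`simtrio`** — a forward simulator of trio cohorts: allele frequencies,
  Mendelian transmission, optional assortative mating and population
  structure, direct/nurture phenotype paths, noisy GWAS summary statistics,
  item-level questionnaire responses and MAR phenotype missingness.
- **`pgs`** — polygenic scoring: p-value–threshold scores with allele
  alignment, a principal-component composite across thresholds (PRS-PC),
  ancestry principal components, and covariate residualization.
- **`pheno`** — an 18-item rating-scale scorer (totals 18–72, prorating,
  completeness rules), predictive-mean-matching multiple imputation and
  Rubin's-rules pooling.
- **`inference`** — unadjusted, trio-adjusted and across-factor OLS with
  robust standard errors, a bootstrap/analytic attenuation (Δβ) test,
  Benjamini–Hochberg FDR and a mechanism classifier.
- **`pipeline` / `cli`** — a YAML-configured, fully deterministic pipeline
  with `simulate → score → impute → fit → report` stages.

Under random mating the analytic identities are simple: the unadjusted
maternal slope equals `m + c/2` (nurture plus half the direct effect, because
mother and child share half their alleles) and the trio adjustment removes
exactly `c/2`. The Δβ test quantifies that attenuation.

## Worked example

```bash
trionurture demo --out demo_run --seed 7
```

simulates 2,000 trios with a direct child effect of 0.15 and a maternal
nurture effect of 0.05, computes threshold polygenic scores from noisy
summary statistics, imputes the partially missing outcome (M = 5) and fits
both models. It prints:

```
Trio polygenic-score analysis: factor 'adhd'

model       role        beta      se              95% CI           p  sig
unadjusted  child      0.214   0.026     [ 0.162, 0.265]    1.07e-14  *
unadjusted  mother     0.126   0.029     [ 0.070, 0.182]    1.69e-05  *
unadjusted  father     0.112   0.027     [ 0.059, 0.166]    4.58e-05  *
trio        child      0.193   0.042     [ 0.111, 0.276]    2.57e-05  *
trio        mother     0.024   0.039     [-0.052, 0.099]       0.538
trio        father     0.016   0.034     [-0.050, 0.083]        0.63

delta-beta (mother): 0.102 (SE 0.023), p = 2.24e-05 [bootstrap]
delta-beta (father): 0.096 (SE 0.021), p = 1.91e-05 [bootstrap]

mechanism (mother): genetic transmission
mechanism (father): genetic transmission
```

Both parents predict the child's outcome in the unadjusted model, but the
associations collapse once the child's own score enters: the parental signal
here was (mostly) transmission. The true maternal nurture path of 0.05 is
within the trio-model confidence interval but too small to detect at this
sample size — the classifier reports the significant attenuation and the
non-significant adjusted coefficient accordingly.

Every stage can also be driven from a YAML config
(`trionurture simulate|score|impute|fit|report --config cfg.yaml --out dir`),
and identical configs give byte-identical outputs.

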