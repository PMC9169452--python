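# duogenie

Does a fetus's own genetic predisposition to higher adult adiposity make it
heavier at birth?  Answering this from GWAS summary statistics is confounded
by the maternal genotype: a child shares half of its mother's alleles, and
maternal adiposity-related variants independently influence birth weight
through the intra-uterine environment.  `duogenie` implements the
summary-statistics pipeline that separates these two channels and estimates
the average per-allele fetal effect of an adiposity instrument set on birth
weight, for epidemiologists and statistical geneticists working with
mother–child data.

## The model

At a biallelic SNP with direct fetal effect β_F and direct maternal effect
β_M on birth weight (SD units), the mother–child dosage correlation of 0.5
implies that unadjusted GWAS estimate

```
E[β_own] = β_F + ½ β_M        (GWAS of one's own birth weight)
E[β_off] = β_M + ½ β_F        (GWAS of offspring birth weight on maternal genotype)
```

Inverting this structural system per SNP (the weighted-linear-model, WLM,
decomposition) gives the maternal-genotype-adjusted fetal effect

```
β_F = (4 β_own − 2 β_off) / 3,   var(β_F) = (16 se_own² + 4 se_off² − 16 cov) / 9
```

(and symmetrically for β_M), with `cov` the sampling covariance of the two
input estimates (0 for non-overlapping samples).  Adjusted per-SNP effects
are aligned to the adult-adiposity-raising allele (resolving allele swaps,
strand flips and — by allele frequency — palindromic SNPs), pooled across
the instrument set by DerSimonian–Laird random-effects meta-analysis
(Cochran's Q, τ², I² reported), and converted from SD units to grams with a
484 g/SD scale.  A weighted linear regression of per-SNP birth-weight
effects on adult-trait effects (weights 1/SE², slope, intercept, adjusted
R²) tests whether birth-weight effects are dose-dependent in the adult
trait.  An individual-level stage fits per-SNP regressions of standardized
perinatal outcomes on child dosage adjusted for maternal dosage, sex and
gestational age in each cohort, pooling cohorts by fixed-effects
meta-analysis.

A mother–child duo simulator (binomial maternal genotypes, uniform allele
transmission, additive fetal/maternal effects) generates every input the
pipeline consumes, so the full analysis runs end to end with no downloads.

## Worked example

```python
import numpy as np
from duogenie import (GenerativeConfig, simulate_duo_cohort, duo_summary_stats,
                      partition_table, overlap_covariance, wlm_to_sumstats,
                      adult_trait_instruments, join_instruments, harmonize_pairs,
                      pool_random, sd_to_grams, fit_weighted_slope)

cfg = GenerativeConfig(n_individuals=150_000, n_snps=14, seed=2)
own, off = duo_summary_stats(simulate_duo_cohort(cfg))
estimates, _ = partition_table(own, off, cov_policy=overlap_covariance(0.5))
fetal = wlm_to_sumstats(estimates, own, which="fetal")
pairs, _ = join_instruments(adult_trait_instruments(cfg), fetal)
harmonized = [p for p in harmonize_pairs(pairs) if not p.dropped]
pooled = sd_to_grams(pool_random([(p.aligned_outcome_beta, p.outcome_se)
                                  for p in harmonized]))
print(f"pooled effect: {pooled.estimate:.2f} g per allele "
      f"(95% CI {pooled.ci_low:.2f}-{pooled.ci_high:.2f}), P = {pooled.pval:.2g}, "
      f"k = {pooled.k}, I2 = {pooled.i2:.1f}%")
fit = fit_weighted_slope([(p.aligned_exposure_beta, p.aligned_outcome_beta,
                           p.outcome_se) for p in harmonized])
print(f"dose-response: slope = {fit.slope:.3f} +/- {fit.slope_se:.3f}, "
      f"adj R2 = {fit.adj_r2:.3f}, P = {fit.pval_slope:.3f}")
```

prints

```
pooled effect: 4.45 g per allele (95% CI 2.52-6.37), P = 5.8e-06, k = 14, I2 = 50.4%
dose-response: slope = 0.414 +/- 0.152, adj R2 = 0.332, P = 0.018
```

The generator's study conditions here put the true mean per-allele fetal
effect at 3.62 g with proportionality slope 0.18, so the pooled estimate
covers the truth within its CI and the regression detects the
dose-dependence; both numbers carry sampling noise from a single simulated
GWAS, which the confidence intervals quantify.  The same stages are exposed
on the command line (`duogenie simulate|join|harmonize|wlm|pool|dose|run`);
`duogenie run --out DIR` executes everything from one config and writes a
reproducibility manifest.

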