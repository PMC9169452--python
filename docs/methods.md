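# Methods

## Structural model and the summary-level partition

The pipeline's target quantity is the direct fetal per-allele effect β_F of
a SNP on birth weight, free of the correlated maternal effect β_M.  Under
additive effects and random mating, a mother–child duo has genotype
correlation 0.5, so the two observable unadjusted GWAS regressions have
expectations β_own = β_F + ½β_M and β_off = β_M + ½β_F.  `partition_effects`
inverts this 2×2 system exactly; variances are propagated through the linear
map, including a covariance term for overlapping input samples:

    var(β_F) = (16 se_own² + 4 se_off² − 16 cov) / 9.

With cov = 0 and equal input SEs s, se(β_F) = (2√5/3)s ≈ 1.49 s — the price
of the adjustment.  When both regressions come from the *same* duos (as in
this package's simulations, where one cohort supplies both tables), the
sampling correlation of the inputs equals the duo genotype correlation, so
`overlap_covariance(0.5)` is the appropriate policy; using cov = 0 there
overstates the SE by ~29% and pushes CI coverage to ~99%.  Real two-source
applications with disjoint samples use the default cov = 0; a scalar or
per-SNP callable supports sensitivity analyses for partial overlap.  The
exact multi-subsample weighting that a consortium analysis would use for
participants contributing own-only, offspring-only or both phenotypes is out
of scope; `combine_subestimates` provides the inverse-variance combination
of per-subset solutions when users have them, and simulation recovery (bias,
SE calibration, CI coverage) is the arbiter of correctness for the two-input
solver.

## Harmonization

Outcome records are aligned to the exposure's effect allele by comparing
allele pairs directly, after swapping, after base complementation, and after
both; a swap negates the beta and maps eaf → 1−eaf.  For palindromic (A/T,
C/G) SNPs the strand is unidentifiable from allele labels, so orientation
falls back to allele frequency: both records must carry an eaf whose
minor-allele frequency is at most `palindrome_freq_limit` (default 0.42, the
customary two-sample threshold — frequencies nearer 0.5 cannot distinguish
the two strand readings); frequencies on the same side of 0.5 keep the sign,
opposite sides flip it, and anything else is dropped rather than guessed.
Whether to frequency-align or simply drop palindromic SNPs is an analysis
choice; both are exposed (`palindromic_policy`), with frequency alignment
the default.  Correctness is established against an independent oracle that
enumerates all swap × strand-flip readings and filters by frequency
consistency.  Indels and multi-allelic variants are rejected at parse time:
the instrument sets this pipeline serves are biallelic SNVs.

Instrument QC removes explicitly excluded SNPs (e.g. a known
disease-collider variant) and prunes pairwise LD above a configurable r²
limit, dropping the member of a pair with the larger exposure p-value (ties
broken lexicographically for determinism); every removal is logged with its
reason so users can override.  LD r² is computed only from user-supplied
dosage vectors as a squared Pearson correlation — no reference panel is
bundled.

## Pooling and heterogeneity

Fixed-effect pooling is inverse-variance weighting; the random-effects
default is DerSimonian–Laird with τ² truncated at 0 and
normal-approximation CIs (±1.96 SE).  I² = max(0, (Q−(k−1))/Q)·100.  DL was
chosen as the field default for "random-effects meta-analysis" when no
estimator is named; an iterative Paule–Mandel estimator is available behind
`method="pm"` for sensitivity.  Whether CIs should use normal or t
quantiles is genuinely open at these k; normal is used and stated here.  No
multiple-testing correction is applied anywhere, matching the exploratory
character of the secondary-outcome analyses; outputs carry all components
(Q, df, τ², I², k) so users can post-process.  The SD→grams conversion is a
fixed linear map with the 484 g/SD birth-weight scale; p-values and I² are
scale-free and unchanged, τ² scales with the square.

## Dose-response regression

`fit_weighted_slope` is weighted least squares of per-SNP outcome betas on
exposure betas with an intercept and weights 1/SE²(outcome) (statsmodels WLS
underneath).  Precision weighting (power 2) is the default because it is the
transform-both-sides reading of "weighted by the inverse of the standard
error"; `weight_power=1` gives literal inverse-SE weighting for sensitivity.
The reported R² is weighted about the weighted mean, and the headline
statistic is *adjusted* R² = 1 − (1−R²)(k−1)/(k−2): unlike plain R² it can
be negative for a non-explanatory fit, and under the null its expectation is
0 for any k, which makes it comparable across the 14-SNP and several-hundred
SNP instrument sets.  The slope p-value uses t with k−2 df.  Regression
through the origin is deliberately not offered: the intercept is part of the
descriptive proportionality question (a nonzero intercept means a uniform
birth-weight shift unrelated to adult-trait magnitude).

## Individual-level cohort stage

Outcomes are z-scored within each cohort on non-missing values (ponderal
index kg/m³ and skinfold sums derived first), so per-allele effects are in
within-cohort SD units and comparable across cohorts that measured traits
differently.  The per-SNP model regresses the standardized outcome on child
dosage, maternal dosage (adjustment for the confounding maternal channel),
sex and gestational age, with listwise deletion (counts reported via
`n_used`) and an explicit rank check that turns silent collinearity into an
error.  Cohorts are pooled per SNP by fixed-effects meta-analysis *before*
any pooling across SNPs, with Q and I² across cohorts reported; the reverse
order is available by composing the library calls differently.  Cord-blood
analytes default to the natural scale with a `log_transform` option, since
no canonical choice exists.  Exclusion rules (birth weight < 2200 g as a
preterm proxy, multiple births, >500 g discrepancy between duplicate
birth-weight reports) are individually toggleable and report per-rule
counts.

## Synthetic duo generator

`simulate_duo_cohort` draws the maternal genotype Binomial(2, f), transmits
one uniformly chosen maternal allele, adds an independent paternal
Bernoulli(f) allele, and builds birth weight additively from child and
maternal dosages plus sex, gestational-age and Gaussian residual terms, in
SD units and grams (484 g/SD around a 3500 g mean).  Default study
conditions emulate a 14-SNP favorable-adiposity instrument: allele
frequencies U(0.1, 0.9), adult-trait effects U(0.015, 0.06) SD/allele with
GWAS-scale standard errors 1/√(2f(1−f)·442 278), fetal effects proportional
to adult effects with slope 0.18 (placing the mean per-allele birth-weight
effect near 3 g ≈ 0.006 SD), no direct maternal effects unless configured,
residual SD 1, and four individual-level cohorts of 4862/1947/674/1867 duos.
Secondary outcomes (length, head circumference, skinfolds, cord insulin)
share a fixed fraction of the birth-weight signal.  SNPs are simulated
without LD (instrument sets are pruned to near-independence by
construction); sex and gestational age are independent of genotype, so they
act as precision covariates, not confounders.  The generator reproduces the
statistical structure the estimators assume — it does not emulate
imputation uncertainty, population stratification, assortative mating,
parent-of-origin effects or selective participation, so passing tests
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data complications.

## Numerical and interface choices

Everything is reproducible from integer seeds (per-cohort streams derived
via SeedSequence); identical config + seed gives bit-identical tables.
Pipeline TSVs are written with 6 significant digits while full precision is
kept in memory; the run manifest records SHA-256 digests of every output so
re-runs can be verified byte for byte.  Chromosome labels are compared as
strings with any `chr` prefix stripped; positions are 1-based and treated as
opaque keys (no liftover — tables from different genome builds must not be
merged).  Missing eaf is representable and tolerated everywhere except
palindromic harmonization, which then fails loudly rather than guessing.
Problem sizes in the test suite and acceptance script (GWAS-scale cohorts of
150 000 duos, 200-replicate calibrations, 1000-replicate null studies) were
chosen so each statistical check has comfortable Monte-Carlo margin while
the whole suite runs in well under a minute.

## Known limitations

The two-input partition assumes exactly additive effects and a duo
correlation of 0.5 (no inbreeding, no assortative mating).  The DL τ² is
noisy at k = 14, and the normal-approximation CI slightly undercovers when
heterogeneity is large.  Frequency-based palindrome orientation can still
mis-orient SNPs whose frequencies differ strongly between studies.  The
headline analyses of real consortium downloads require those files; this
package validates the machinery on synthetic equivalents with known truth.
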