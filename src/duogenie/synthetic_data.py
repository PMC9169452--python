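"""Simulate mother-child duo cohorts and GWAS-style summary statistics.

The generator embodies the transmission model the whole analysis relies on:
the mother's genotype at a biallelic SNP is Binomial(2, f); the child inherits
one uniformly chosen maternal allele plus an independent paternal allele drawn
at the population frequency.  This makes the child-mother dosage correlation
0.5, which is exactly why an unadjusted GWAS of one's own birth weight picks
up half of any maternal effect (and vice versa).

Birth weight (in SD units) is additive in child and maternal dosages:

    bw = sum_j beta_F[j]*(c_j - 2 f_j) + beta_M[j]*(m_j - 2 f_j)
         + a_sex*sex + a_ga*(ga - mean_ga) + Normal(0, noise_sd)

and is also reported in grams on a 484 g/SD scale.  Per-SNP fetal effects are
proportional to the SNP's adult-adiposity effect (slope configurable, with
optional per-SNP deviations), so the dose-response stage has a known truth.
Secondary perinatal outcomes share a configurable fraction of the genetic
signal.  SNPs are mutually independent (no LD) by default, mirroring
instrument sets pruned to pairwise r² <= 0.05; an optional correlated
duplicate SNP supports testing LD-based instrument filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .snp_pooling import BIRTH_WEIGHT_SD_GRAMS
from .sumstats_io import InstrumentSet, SumStatRecord

__all__ = [
    "GenerativeConfig",
    "DuoCohort",
    "simulate_duo_cohort",
    "simulate_cohorts",
    "duo_summary_stats",
    "adult_trait_instruments",
    "DEFAULT_COHORT_SIZES",
    "DEFAULT_COHORT_LABELS",
]

# Mother-child duo counts on the scale of the four pregnancy cohorts the
# individual-level stage emulates.
DEFAULT_COHORT_SIZES = (4862, 1947, 674, 1867)
DEFAULT_COHORT_LABELS = ("cohortA", "cohortB", "cohortC", "cohortD")

# secondary outcomes: (mean, SD in natural units, share of the birth-weight
# genetic+environmental signal carried over)
OUTCOME_SPECS: dict[str, tuple[float, float, float]] = {
    "birth_length_cm": (50.0, 2.4, 0.6),
    "head_circumference_cm": (35.0, 1.5, 0.4),
    "triceps_skinfold_mm": (5.5, 1.6, 0.3),
    "subscapular_skinfold_mm": (5.0, 1.5, 0.3),
    "cord_insulin_pmol_l": (40.0, 22.0, 0.15),
}

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T"))


@dataclass
class GenerativeConfig:
    """Parameters of the duo-simulation study conditions.

    Defaults emulate a 14-SNP metabolically-favorable-adiposity instrument
    set: adult-trait effects of a few hundredths of an SD per allele, fetal
    birth-weight effects proportional to them with a slope that puts the mean
    per-allele effect at roughly 3 g (0.006 SD), no direct maternal effects,
    and residual birth-weight noise of 1 SD.
    """

    n_individuals: int = 4862
    n_snps: int = 14
    allele_freqs: np.ndarray | None = None  # default U(0.1, 0.9) from seed
    adult_trait_betas: np.ndarray | None = None  # default U(0.015, 0.06) SD/allele
    proportionality_slope: float = 0.18  # birth-weight SD per adult-trait SD
    beta_fetal: np.ndarray | None = None  # overrides slope * adult_trait_betas
    beta_maternal: np.ndarray | float = 0.0
    fetal_noise_sd: float = 0.0  # per-SNP deviation from proportionality
    noise_sd: float = 1.0  # residual birth-weight SD (SD units)
    sex_effect_sd: float = 0.15  # male minus female birth weight
    ga_effect_sd_per_week: float = 0.15
    mean_ga_weeks: float = 39.5
    sd_ga_weeks: float = 1.3
    mean_bw_grams: float = 3500.0
    sd_grams: float = BIRTH_WEIGHT_SD_GRAMS
    include_multiple_births: bool = False
    multiple_birth_rate: float = 0.02
    report_error_sd_g: float = 0.0  # >0 adds a noisy second birth-weight report
    adult_trait_n: int = 442_278
    include_palindromic: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ConfigError("n_individuals and n_snps must be positive")
        if self.noise_sd <= 0 or self.sd_grams <= 0 or self.sd_ga_weeks <= 0:
            raise ConfigError("noise/scale SDs must be > 0")
        freqs = self.resolved_freqs()
        if np.any(freqs <= 0) or np.any(freqs >= 1):
            raise ConfigError("allele frequencies must lie strictly in (0, 1)")

    # --- resolved per-SNP arrays (deterministic in the seed) -------------
    def _rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    def resolved_freqs(self) -> np.ndarray:
        if self.allele_freqs is not None:
            return np.broadcast_to(np.asarray(self.allele_freqs, float), (self.n_snps,)).copy()
        return self._rng(1).uniform(0.1, 0.9, self.n_snps)

    def resolved_adult_betas(self) -> np.ndarray:
        if self.adult_trait_betas is not None:
            return np.broadcast_to(np.asarray(self.adult_trait_betas, float), (self.n_snps,)).copy()
        return self._rng(2).uniform(0.015, 0.06, self.n_snps)

    def resolved_beta_fetal(self) -> np.ndarray:
        if self.beta_fetal is not None:
            return np.broadcast_to(np.asarray(self.beta_fetal, float), (self.n_snps,)).copy()
        base = self.proportionality_slope * self.resolved_adult_betas()
        if self.fetal_noise_sd > 0:
            base = base + self._rng(3).normal(0.0, self.fetal_noise_sd, self.n_snps)
        return base

    def resolved_beta_maternal(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.beta_maternal, float), (self.n_snps,)).copy()

    def snp_ids(self) -> list[str]:
        return [f"rs{100001 + 37 * j}" for j in range(self.n_snps)]

    def snp_alleles(self) -> list[tuple[str, str]]:
        pairs = []
        rng = self._rng(4)
        for j in range(self.n_snps):
            if self.include_palindromic and j % 5 == 4:
                pairs.append(("A", "T") if j % 2 else ("C", "G"))
            else:
                pairs.append(_NONPALINDROMIC_PAIRS[int(rng.integers(len(_NONPALINDROMIC_PAIRS)))])
        return pairs


@dataclass
class DuoCohort:
    """One simulated mother-child cohort.

    ``data`` holds one row per duo: child dosages ``c_<rsid>``, maternal
    dosages ``m_<rsid>``, outcomes in natural units plus ``birth_weight_sd``,
    ``sex`` (1 = male), ``gestational_age`` (weeks), and exclusion-relevant
    fields when enabled.
    """

    cohort: str
    data: pd.DataFrame
    snp_ids: list[str]
    outcome_columns: list[str]
    allele_freqs: np.ndarray
    seed: int
    alleles: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.data)

    def child_dosage(self, snp_id: str) -> np.ndarray:
        return self.data[f"c_{snp_id}"].to_numpy(float)

    def maternal_dosage(self, snp_id: str) -> np.ndarray:
        return self.data[f"m_{snp_id}"].to_numpy(float)


def simulate_duo_cohort(
    config: GenerativeConfig,
    label: str = "cohortA",
    seed: int | None = None,
) -> DuoCohort:
    """Draw one duo cohort under the transmission model.

    Fully reproducible: the same config and seed give a bit-identical table.
    ``seed`` overrides ``config.seed`` for per-cohort streams.
    """
    config.validate()
    used_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([used_seed, 100]))
    n, p = config.n_individuals, config.n_snps
    freqs = config.resolved_freqs()
    bf = config.resolved_beta_fetal()
    bm = config.resolved_beta_maternal()

    maternal = rng.binomial(2, freqs, size=(n, p)).astype(np.int8)
    transmitted = rng.binomial(1, maternal / 2.0)
    paternal = rng.binomial(1, freqs, size=(n, p))
    child = (transmitted + paternal).astype(np.int8)

    sex = rng.integers(0, 2, n)  # 1 = male
    ga = rng.normal(config.mean_ga_weeks, config.sd_ga_weeks, n)

    genetic = (child - 2 * freqs) @ bf + (maternal - 2 * freqs) @ bm
    env = rng.normal(0.0, config.noise_sd, n)
    bw_sd = (
        genetic
        + env
        + config.sex_effect_sd * (sex - 0.5)
        + config.ga_effect_sd_per_week * (ga - config.mean_ga_weeks)
    )
    bw_g = config.mean_bw_grams + config.sd_grams * bw_sd

    cols: dict[str, np.ndarray] = {
        "sex": sex,
        "gestational_age": ga,
        "birth_weight_sd": bw_sd,
        "birth_weight_g": bw_g,
    }
    outcome_cols = ["birth_weight_sd", "birth_weight_g"]
    shared = genetic + env  # genetic + shared environment driving all outcomes
    for name, (mean, sd_nat, share) in OUTCOME_SPECS.items():
        own_noise = rng.normal(0.0, math.sqrt(max(1e-12, 1.0 - share**2)), n)
        cols[name] = mean + sd_nat * (share * shared + own_noise)
        outcome_cols.append(name)

    if config.include_multiple_births:
        cols["multiple_birth"] = rng.binomial(1, config.multiple_birth_rate, n)
    if config.report_error_sd_g > 0:
        cols["birth_weight_g_report2"] = bw_g + rng.normal(0.0, config.report_error_sd_g, n)

    ids = config.snp_ids()
    for j, snp in enumerate(ids):
        cols[f"m_{snp}"] = maternal[:, j]
        cols[f"c_{snp}"] = child[:, j]

    frame = pd.DataFrame(cols)
    frame.insert(0, "id", [f"{label}-{i:06d}" for i in range(n)])
    return DuoCohort(
        cohort=label,
        data=frame,
        snp_ids=ids,
        outcome_columns=outcome_cols,
        allele_freqs=freqs,
        seed=used_seed,
        alleles=config.snp_alleles(),
    )


def simulate_cohorts(
    config: GenerativeConfig,
    sizes: Sequence[int] = DEFAULT_COHORT_SIZES,
    labels: Sequence[str] = DEFAULT_COHORT_LABELS,
) -> list[DuoCohort]:
    """Simulate several cohorts of differing size sharing the same genetics."""
    if len(sizes) != len(labels):
        raise ConfigError("sizes and labels must have equal length")
    cohorts = []
    for i, (n, label) in enumerate(zip(sizes, labels)):
        cfg = _with_n(config, n)
        cohorts.append(simulate_duo_cohort(cfg, label=label, seed=config.seed * 1000 + i))
    return cohorts


def _with_n(config: GenerativeConfig, n: int) -> GenerativeConfig:
    import dataclasses

    return dataclasses.replace(config, n_individuals=n)


def _simple_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, SE and two-sided p of y ~ x (with intercept), closed form."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = math.sqrt(sigma2 / sxx)
    t = beta / se
    pval = 2.0 * stats.t.sf(abs(t), n - 2)
    return beta, se, max(pval, 5e-324)


def duo_summary_stats(
    cohort: DuoCohort,
    outcome: str = "birth_weight_sd",
) -> tuple[list[SumStatRecord], list[SumStatRecord]]:
    """Per-SNP GWAS-style tables of own and offspring birth weight.

    For each SNP the child outcome is regressed on the child dosage (the
    "own birth weight" GWAS) and on the maternal dosage (the "offspring birth
    weight" GWAS of maternal genotype), emulating the two unadjusted summary
    inputs of the maternal/fetal partition.  Monomorphic SNPs are dropped with
    a warning.  Effect allele is the counted (alternate) allele.
    """
    if cohort.n < 100:
        raise ValidationError(f"cohort {cohort.cohort}: n >= 100 required for summary stats")
    y = cohort.data[outcome].to_numpy(float)
    own: list[SumStatRecord] = []
    off: list[SumStatRecord] = []
    alleles = cohort.alleles or [("A", "G")] * len(cohort.snp_ids)
    for j, snp in enumerate(cohort.snp_ids):
        c = cohort.child_dosage(snp)
        m = cohort.maternal_dosage(snp)
        if np.ptp(c) == 0 or np.ptp(m) == 0:
            import warnings

            warnings.warn(f"{snp}: monomorphic in cohort {cohort.cohort}; dropped")
            continue
        ea, oa = alleles[j]
        common = dict(
            snp_id=snp,
            chrom=str(j % 22 + 1),
            pos=1_000_000 + 10_000 * j,
            effect_allele=ea,
            other_allele=oa,
            n=cohort.n,
        )
        b, se, p = _simple_regression(c, y)
        own.append(SumStatRecord(eaf=float(c.mean() / 2), beta=b, se=se, pval=p, **common))
        b, se, p = _simple_regression(m, y)
        off.append(SumStatRecord(eaf=float(m.mean() / 2), beta=b, se=se, pval=p, **common))
    return own, off


def adult_trait_instruments(
    config: GenerativeConfig,
    name: str = "favorable-adiposity-synthetic",
    trait_units: str = "SD body fat %",
) -> InstrumentSet:
    """Instrument list for the simulated adult adiposity trait.

    Effect sizes are the configured per-allele adult-trait effects with the
    raising allele as effect allele; standard errors follow the large-GWAS
    approximation se = 1/sqrt(2 f (1-f) n) for a standardized trait.
    """
    freqs = config.resolved_freqs()
    betas = config.resolved_adult_betas()
    ids = config.snp_ids()
    alleles = config.snp_alleles()
    records = []
    for j, snp in enumerate(ids):
        se = 1.0 / math.sqrt(2.0 * freqs[j] * (1.0 - freqs[j]) * config.adult_trait_n)
        z = betas[j] / se
        pval = max(2.0 * stats.norm.sf(abs(z)), 5e-324)
        records.append(
            SumStatRecord(
                snp_id=snp,
                chrom=str(j % 22 + 1),
                pos=1_000_000 + 10_000 * j,
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                eaf=float(freqs[j]),
                beta=float(betas[j]),
                se=se,
                pval=pval,
                n=config.adult_trait_n,
            )
        )
    return InstrumentSet(name=name, records=tuple(records), trait_units=trait_units)
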