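"""Partition GWAS birth-weight effects into fetal and maternal components.

A child carries half of its mother's alleles, so an unadjusted GWAS of one's
own birth weight estimates beta_own = beta_F + beta_M/2 and a GWAS of
offspring birth weight (on maternal genotype) estimates beta_off =
beta_M + beta_F/2, where beta_F and beta_M are the direct fetal and maternal
per-allele effects.  Inverting this 2x2 structural system per SNP gives the
maternal-genotype-adjusted fetal effect (and vice versa) from summary data
alone — the weighted-linear-model (WLM) decomposition:

    beta_F = (4*beta_own - 2*beta_off) / 3
    beta_M = (4*beta_off - 2*beta_own) / 3

with variances propagated through the same linear map.  When the two input
GWAS share samples the input estimates are correlated and the covariance term
matters; ``cov_policy`` controls it (0 for non-overlapping samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from scipy import stats

from .errors import HarmonizationRequiredError, PropagationError, ValidationError
from .sumstats_io import SumStatRecord

__all__ = [
    "WlmEstimate",
    "partition_effects",
    "partition_table",
    "combine_subestimates",
    "wlm_to_sumstats",
    "overlap_covariance",
]


@dataclass(frozen=True)
class WlmEstimate:
    """Maternal-adjusted fetal and fetal-adjusted maternal effect for one SNP."""

    snp_id: str
    beta_fetal: float
    se_fetal: float
    beta_maternal: float
    se_maternal: float
    cov_inputs: float = 0.0

    def __post_init__(self) -> None:
        if not (self.se_fetal > 0 and self.se_maternal > 0):
            raise PropagationError(
                f"{self.snp_id}: non-positive adjusted standard error "
                f"(se_fetal={self.se_fetal}, se_maternal={self.se_maternal})"
            )


def partition_effects(
    beta_own: float,
    se_own: float,
    beta_off: float,
    se_off: float,
    cov: float = 0.0,
    snp_id: str = "",
) -> WlmEstimate:
    """Solve the structural system for one SNP.

    ``cov`` is the sampling covariance between the own-birth-weight and
    offspring-birth-weight estimates: 0 for independent samples, up to
    r*se_own*se_off when the same mother-child duos contribute to both
    regressions (r is the sampling correlation, ~0.5 for complete overlap,
    matching the duo genotype correlation).
    """
    if not (se_own > 0 and se_off > 0):
        raise ValidationError(f"{snp_id}: input standard errors must be > 0")
    beta_fetal = (4.0 * beta_own - 2.0 * beta_off) / 3.0
    beta_maternal = (4.0 * beta_off - 2.0 * beta_own) / 3.0
    var_fetal = (16.0 * se_own**2 + 4.0 * se_off**2 - 16.0 * cov) / 9.0
    var_maternal = (16.0 * se_off**2 + 4.0 * se_own**2 - 16.0 * cov) / 9.0
    if var_fetal <= 0 or var_maternal <= 0:
        raise PropagationError(
            f"{snp_id}: covariance {cov} yields non-positive adjusted variance "
            f"(var_fetal={var_fetal:g}, var_maternal={var_maternal:g})"
        )
    return WlmEstimate(
        snp_id=snp_id,
        beta_fetal=beta_fetal,
        se_fetal=math.sqrt(var_fetal),
        beta_maternal=beta_maternal,
        se_maternal=math.sqrt(var_maternal),
        cov_inputs=cov,
    )


def overlap_covariance(r: float) -> Callable[[SumStatRecord, SumStatRecord], float]:
    """Covariance policy ``cov = r * se_own * se_off`` for overlapping samples."""
    return lambda own, off: r * own.se * off.se


def partition_table(
    own: Sequence[SumStatRecord],
    off: Sequence[SumStatRecord],
    cov_policy: float | Callable[[SumStatRecord, SumStatRecord], float] = 0.0,
) -> tuple[list[WlmEstimate], list[str]]:
    """Partition every SNP present in both tables.

    Both tables must already be expressed on the same effect allele per SNP —
    this is asserted, not assumed.  Returns ``(estimates, missing_ids)`` with
    missing_ids the SNPs of ``own`` absent from ``off``.
    """
    off_by_id = {r.snp_id: r for r in off}
    estimates: list[WlmEstimate] = []
    missing: list[str] = []
    for own_rec in own:
        off_rec = off_by_id.get(own_rec.snp_id)
        if off_rec is None:
            missing.append(own_rec.snp_id)
            continue
        if (own_rec.effect_allele, own_rec.other_allele) != (
            off_rec.effect_allele,
            off_rec.other_allele,
        ):
            raise HarmonizationRequiredError(
                f"{own_rec.snp_id}: effect-allele mismatch between own "
                f"({own_rec.effect_allele}/{own_rec.other_allele}) and offspring "
                f"({off_rec.effect_allele}/{off_rec.other_allele}) tables; harmonize first"
            )
        cov = cov_policy(own_rec, off_rec) if callable(cov_policy) else float(cov_policy)
        estimates.append(
            partition_effects(
                own_rec.beta, own_rec.se, off_rec.beta, off_rec.se, cov=cov, snp_id=own_rec.snp_id
            )
        )
    return estimates, missing


def combine_subestimates(
    estimates: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Inverse-variance combination of independent sub-sample estimates.

    Supports the case where separate WLM solutions are available for distinct
    participant subsets (e.g. duos with both phenotypes, own-birth-weight-only,
    offspring-only): each contributes with weight 1/se².
    """
    if len(estimates) < 1:
        raise ValidationError("at least one sub-estimate required")
    weights = [1.0 / se**2 for _, se in estimates]
    total = sum(weights)
    beta = sum(w * b for w, (b, _) in zip(weights, estimates)) / total
    return beta, math.sqrt(1.0 / total)


def wlm_to_sumstats(
    estimates: Sequence[WlmEstimate],
    template: Sequence[SumStatRecord],
    which: str = "fetal",
) -> list[SumStatRecord]:
    """Express WLM output as summary-stat records (alleles/eaf from ``template``).

    Downstream stages then consume WLM output and public maternal-adjusted
    GWAS downloads identically.  ``which`` selects the fetal or maternal
    component; p-values are two-sided normal.
    """
    if which not in ("fetal", "maternal"):
        raise ValueError("which must be 'fetal' or 'maternal'")
    by_id = {r.snp_id: r for r in template}
    out: list[SumStatRecord] = []
    for est in estimates:
        tmpl = by_id.get(est.snp_id)
        if tmpl is None:
            raise HarmonizationRequiredError(f"{est.snp_id}: no template record for allele labels")
        beta = est.beta_fetal if which == "fetal" else est.beta_maternal
        se = est.se_fetal if which == "fetal" else est.se_maternal
        pval = 2.0 * stats.norm.sf(abs(beta) / se)
        out.append(
            SumStatRecord(
                snp_id=est.snp_id,
                chrom=tmpl.chrom,
                pos=tmpl.pos,
                effect_allele=tmpl.effect_allele,
                other_allele=tmpl.other_allele,
                eaf=tmpl.eaf,
                beta=beta,
                se=se,
                pval=max(pval, 5e-324),
                n=tmpl.n,
            )
        )
    return out
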