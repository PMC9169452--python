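"""Allele harmonization of two-sample summary statistics, plus instrument QC.

Aligns outcome-trait effect estimates so the effect allele matches the
exposure record's effect allele (in this pipeline: the adult-adiposity-raising
allele), resolving allele-order swaps, strand flips, and — by allele frequency
— palindromic (A/T, C/G) SNPs whose strand is ambiguous in summary data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import AlleleMismatchError, DegenerateInputError, UnresolvableAlleleError
from .sumstats_io import InstrumentSet, SumStatRecord

__all__ = [
    "HarmonizedPair",
    "harmonize_record",
    "harmonize_pairs",
    "pairwise_ld_r2",
    "filter_instruments",
    "is_palindromic",
    "DEFAULT_PALINDROME_FREQ_LIMIT",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Minor-allele-frequency ceiling for frequency-based orientation of palindromic
# SNPs: above it the two strand readings are too close to distinguish.  0.42 is
# the customary two-sample harmonization default.
DEFAULT_PALINDROME_FREQ_LIMIT = 0.42


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects expressed on the same physical allele.

    ``resolution`` records how the alignment was achieved: ``direct``,
    ``swap``, ``strand_flip``, ``strand_flip_swap``, ``palindromic_freq`` or
    ``dropped`` (palindromic and unresolvable under the chosen policy; no
    betas are carried).
    """

    snp_id: str
    resolution: str
    aligned_exposure_beta: float | None = None
    exposure_se: float | None = None
    aligned_outcome_beta: float | None = None
    outcome_se: float | None = None
    aligned_outcome_eaf: float | None = None

    @property
    def dropped(self) -> bool:
        return self.resolution == "dropped"


def is_palindromic(record: SumStatRecord) -> bool:
    """True for A/T and C/G variants, whose strand cannot be inferred from alleles."""
    return COMPLEMENT[record.effect_allele] == record.other_allele


def harmonize_record(
    exposure: SumStatRecord,
    outcome: SumStatRecord,
    palindrome_freq_limit: float = DEFAULT_PALINDROME_FREQ_LIMIT,
    palindromic_policy: str = "frequency",
) -> HarmonizedPair:
    """Align one outcome record to the exposure record's effect allele.

    Allele pairs are compared directly, after swapping, after base
    complementation, and after both; a swap negates the outcome beta and maps
    eaf to 1-eaf.  Palindromic SNPs are oriented by allele frequency
    (``palindromic_policy="frequency"``): both records must carry an eaf with
    minor-allele frequency <= ``palindrome_freq_limit``; frequencies on the
    same side of 0.5 mean the reported effect alleles already match, opposite
    sides mean the outcome is reported on the complementary strand's other
    allele and the beta flips sign.  ``palindromic_policy="drop"`` discards
    all palindromic SNPs instead.
    """
    if exposure.snp_id != outcome.snp_id:
        raise AlleleMismatchError(
            f"cannot harmonize different SNPs {exposure.snp_id!r} vs {outcome.snp_id!r}"
        )
    if palindromic_policy not in ("frequency", "drop"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy!r}")

    exp_pair = (exposure.effect_allele, exposure.other_allele)
    out_pair = (outcome.effect_allele, outcome.other_allele)
    out_comp = (COMPLEMENT[outcome.effect_allele], COMPLEMENT[outcome.other_allele])

    if is_palindromic(exposure) or is_palindromic(outcome):
        if {*exp_pair} != {*out_pair}:
            raise AlleleMismatchError(
                f"{exposure.snp_id}: irreconcilable alleles "
                f"{exp_pair[0]}/{exp_pair[1]} vs {out_pair[0]}/{out_pair[1]}"
            )
        if palindromic_policy == "drop":
            return HarmonizedPair(snp_id=exposure.snp_id, resolution="dropped")
        return _resolve_palindromic(exposure, outcome, palindrome_freq_limit)

    # The literal allele labels decide; eaf plays no role for non-palindromic SNPs.
    if out_pair == exp_pair:
        aligned, resolution = outcome, "direct"
    elif (out_pair[1], out_pair[0]) == exp_pair:
        aligned, resolution = outcome.flipped(), "swap"
    elif out_comp == exp_pair:
        aligned, resolution = outcome, "strand_flip"
    elif (out_comp[1], out_comp[0]) == exp_pair:
        aligned, resolution = outcome.flipped(), "strand_flip_swap"
    else:
        raise AlleleMismatchError(
            f"{exposure.snp_id}: irreconcilable alleles "
            f"{exp_pair[0]}/{exp_pair[1]} vs {out_pair[0]}/{out_pair[1]}"
        )
    return HarmonizedPair(
        snp_id=exposure.snp_id,
        resolution=resolution,
        aligned_exposure_beta=exposure.beta,
        exposure_se=exposure.se,
        aligned_outcome_beta=aligned.beta,
        outcome_se=aligned.se,
        aligned_outcome_eaf=aligned.eaf,
    )


def _resolve_palindromic(
    exposure: SumStatRecord,
    outcome: SumStatRecord,
    freq_limit: float,
) -> HarmonizedPair:
    if exposure.eaf is None or outcome.eaf is None:
        raise UnresolvableAlleleError(
            f"{exposure.snp_id}: palindromic SNP with missing allele frequency "
            "cannot be oriented"
        )
    maf_exp = min(exposure.eaf, 1.0 - exposure.eaf)
    maf_out = min(outcome.eaf, 1.0 - outcome.eaf)
    if maf_exp > freq_limit or maf_out > freq_limit:
        return HarmonizedPair(snp_id=exposure.snp_id, resolution="dropped")
    same_side = (exposure.eaf - 0.5) * (outcome.eaf - 0.5) > 0
    aligned = outcome if same_side else outcome.flipped()
    return HarmonizedPair(
        snp_id=exposure.snp_id,
        resolution="palindromic_freq",
        aligned_exposure_beta=exposure.beta,
        exposure_se=exposure.se,
        aligned_outcome_beta=aligned.beta,
        outcome_se=aligned.se,
        aligned_outcome_eaf=aligned.eaf,
    )


def harmonize_pairs(
    pairs: Iterable[tuple[SumStatRecord, SumStatRecord]],
    palindrome_freq_limit: float = DEFAULT_PALINDROME_FREQ_LIMIT,
    palindromic_policy: str = "frequency",
    orient_to_raising: bool = True,
) -> list[HarmonizedPair]:
    """Harmonize a joined (instrument, outcome) table record by record.

    With ``orient_to_raising`` the exposure record is first flipped, where
    necessary, so its beta is non-negative — i.e. the shared effect allele is
    the adult-trait-raising allele, the orientation the pooled per-allele
    birth-weight effect is reported on.
    """
    out: list[HarmonizedPair] = []
    for exposure, outcome in pairs:
        if orient_to_raising and exposure.beta < 0:
            exposure = exposure.flipped()
        out.append(
            harmonize_record(
                exposure,
                outcome,
                palindrome_freq_limit=palindrome_freq_limit,
                palindromic_policy=palindromic_policy,
            )
        )
    return out


def pairwise_ld_r2(dosages_a: Sequence[float], dosages_b: Sequence[float]) -> float:
    """Squared Pearson correlation (LD r²) between two per-individual dosage vectors."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise DegenerateInputError("dosage vectors must be 1-D, equal length and n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant dosage vector: LD r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def filter_instruments(
    instruments: InstrumentSet,
    exclude_ids: Sequence[str] = (),
    ld_pairs: Sequence[tuple[str, str, float]] = (),
    r2_limit: float = 0.05,
) -> tuple[InstrumentSet, list[tuple[str, str]]]:
    """Apply explicit exclusions and pairwise-LD pruning to an instrument set.

    For each supplied LD pair with r² above ``r2_limit`` the member with the
    larger exposure p-value is dropped (the less strongly associated
    instrument).  Every removal is returned in the ``(snp_id, reason)`` log so
    users can audit or override; an exclude_id absent from the set warns but
    does not error.
    """
    log: list[tuple[str, str]] = []
    present = set(instruments.snp_ids)
    removed: set[str] = set()

    for snp_id in exclude_ids:
        if snp_id not in present:
            warnings.warn(f"exclude_id {snp_id!r} not in instrument set '{instruments.name}'")
            continue
        if snp_id not in removed:
            removed.add(snp_id)
            log.append((snp_id, "explicit exclusion"))

    pvals = {r.snp_id: r.pval for r in instruments.records}
    for id_a, id_b, r2 in ld_pairs:
        if r2 <= r2_limit:
            continue
        candidates = [i for i in (id_a, id_b) if i in present and i not in removed]
        if len(candidates) < 2:
            continue
        # drop the weaker instrument; ties broken lexicographically for determinism
        victim = max(candidates, key=lambda i: (pvals.get(i, math.inf), i))
        removed.add(victim)
        log.append((victim, f"LD with {id_a if victim == id_b else id_b} (r2={r2:g} > {r2_limit:g})"))

    kept = tuple(r for r in instruments.records if r.snp_id not in removed)
    return (
        InstrumentSet(name=instruments.name, records=kept, trait_units=instruments.trait_units),
        log,
    )
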