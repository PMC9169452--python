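"""Meta-analytic pooling of per-allele effects and SD-to-grams conversion.

Pooling across the SNPs of an instrument set yields the average per-allele
effect of the genetic predisposition on the outcome ("pooled genetic
effect").  Fixed-effect pooling is inverse-variance weighting; random-effects
pooling uses the DerSimonian-Laird moment estimator of the between-SNP
variance tau².  Heterogeneity is summarized by Cochran's Q and I².  Birth
weight effects estimated in SD units are converted to grams with a fixed
484 g per SD scale (the average birth-weight SD across early GWAS cohorts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from scipy import stats

from .errors import InsufficientInputError, ValidationError

__all__ = ["PooledEffect", "pool_fixed", "pool_random", "sd_to_grams", "BIRTH_WEIGHT_SD_GRAMS"]

BIRTH_WEIGHT_SD_GRAMS = 484.0

_Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class PooledEffect:
    """Pooled per-allele effect with 95% CI and heterogeneity statistics."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    k: int
    q_stat: float
    q_df: int
    tau2: float
    i2: float
    model: str

    def scaled(self, factor: float) -> "PooledEffect":
        """Multiply the effect scale by ``factor`` (Q, I², p are scale-free)."""
        return replace(
            self,
            estimate=self.estimate * factor,
            se=self.se * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
            tau2=self.tau2 * factor**2,
        )


def _check(estimates: Sequence[tuple[float, float]]) -> None:
    if len(estimates) < 2:
        raise InsufficientInputError(f"pooling requires k >= 2 estimates, got {len(estimates)}")
    for i, (_, se) in enumerate(estimates):
        if not se > 0:
            raise ValidationError(f"estimate {i}: se must be > 0, got {se}")


def pool_fixed(estimates: Sequence[tuple[float, float]]) -> PooledEffect:
    """Inverse-variance fixed-effect pooling of ``(beta, se)`` pairs.

    Weights w_i = 1/se_i²; the pooled estimate is the weighted mean, its
    standard error 1/sqrt(sum w_i); Q = sum w_i (b_i - pooled)² with k-1 df.
    """
    _check(estimates)
    w = [1.0 / se**2 for _, se in estimates]
    total_w = sum(w)
    estimate = sum(wi * b for wi, (b, _) in zip(w, estimates)) / total_w
    se = math.sqrt(1.0 / total_w)
    q = sum(wi * (b - estimate) ** 2 for wi, (b, _) in zip(w, estimates))
    k = len(estimates)
    return _finish(estimate, se, k, q, tau2=0.0, model="fixed")


def pool_random(estimates: Sequence[tuple[float, float]], method: str = "dl") -> PooledEffect:
    """Random-effects pooling of ``(beta, se)`` pairs.

    ``method="dl"`` (default): DerSimonian-Laird moment estimator,

        tau² = max(0, (Q - (k-1)) / (sum w - sum w² / sum w)),

    with fixed-effect weights w_i = 1/se_i²; the estimate is then re-pooled
    with w*_i = 1/(se_i² + tau²).  ``method="pm"`` iterates the Paule-Mandel
    (empirical REML-type) estimator instead.  I² = max(0, (Q-(k-1))/Q)·100.
    """
    _check(estimates)
    w = [1.0 / se**2 for _, se in estimates]
    total_w = sum(w)
    fixed_est = sum(wi * b for wi, (b, _) in zip(w, estimates)) / total_w
    q = sum(wi * (b - fixed_est) ** 2 for wi, (b, _) in zip(w, estimates))
    k = len(estimates)

    if method == "dl":
        denom = total_w - sum(wi**2 for wi in w) / total_w
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    elif method == "pm":
        tau2 = _paule_mandel_tau2(estimates)
    else:
        raise ValueError(f"unknown random-effects method {method!r}")

    w_star = [1.0 / (se**2 + tau2) for _, se in estimates]
    total_ws = sum(w_star)
    estimate = sum(wi * b for wi, (b, _) in zip(w_star, estimates)) / total_ws
    se = math.sqrt(1.0 / total_ws)
    return _finish(estimate, se, k, q, tau2=tau2, model="random")


def _paule_mandel_tau2(
    estimates: Sequence[tuple[float, float]],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Paule-Mandel tau²: solve Q_gen(tau²) = k - 1 by fixed-point iteration."""
    k = len(estimates)
    tau2 = 0.0
    for _ in range(max_iter):
        w = [1.0 / (se**2 + tau2) for _, se in estimates]
        total = sum(w)
        mu = sum(wi * b for wi, (b, _) in zip(w, estimates)) / total
        q_gen = sum(wi * (b - mu) ** 2 for wi, (b, _) in zip(w, estimates))
        if q_gen <= k - 1:
            if tau2 == 0.0:
                return 0.0
            step = (q_gen - (k - 1)) / sum(wi**2 for wi in w)
            tau2 = max(0.0, tau2 + step)
        else:
            tau2 += (q_gen - (k - 1)) / sum(wi**2 for wi in w)
        if abs(q_gen - (k - 1)) < tol:
            break
    return max(0.0, tau2)


def _finish(estimate: float, se: float, k: int, q: float, tau2: float, model: str) -> PooledEffect:
    z = estimate / se
    pval = 2.0 * stats.norm.sf(abs(z))
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return PooledEffect(
        estimate=estimate,
        se=se,
        ci_low=estimate - _Z95 * se,
        ci_high=estimate + _Z95 * se,
        pval=max(pval, 5e-324),
        k=k,
        q_stat=q,
        q_df=k - 1,
        tau2=tau2,
        i2=i2,
        model=model,
    )


def sd_to_grams(
    effect: PooledEffect | tuple[float, float],
    sd_grams: float = BIRTH_WEIGHT_SD_GRAMS,
) -> PooledEffect | tuple[float, float]:
    """Convert an SD-unit effect (pooled or a bare ``(beta, se)``) to grams."""
    if not sd_grams > 0:
        raise ValidationError(f"sd_grams must be > 0, got {sd_grams}")
    if isinstance(effect, PooledEffect):
        return effect.scaled(sd_grams)
    beta, se = effect
    return beta * sd_grams, se * sd_grams
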