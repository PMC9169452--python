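"""Individual-level mother-child analyses within and across cohorts.

Per cohort: z-score each perinatal/cord-blood outcome (within-cohort, so
estimates are comparable across cohorts that measured the trait differently),
then regress it on the child's dosage adjusting for maternal dosage, the
child's sex and gestational age.  Per SNP and outcome, cohort estimates are
pooled by inverse-variance fixed-effects meta-analysis with Cochran's Q and
I² quantifying between-cohort heterogeneity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, InsufficientInputError, IntegrityError, ValidationError
from .snp_pooling import PooledEffect, pool_fixed
from .synthetic_data import DuoCohort

__all__ = [
    "CohortAssoc",
    "standardize_outcomes",
    "fit_snp_model",
    "meta_across_cohorts",
    "apply_exclusions",
    "ponderal_index",
]


@dataclass(frozen=True)
class CohortAssoc:
    """Per-allele effect of one SNP on one standardized outcome in one cohort."""

    cohort: str
    snp_id: str
    outcome: str
    beta: float
    se: float
    n_used: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"{self.cohort}/{self.snp_id}/{self.outcome}: se must be > 0")


def ponderal_index(weight_kg: np.ndarray, length_m: np.ndarray) -> np.ndarray:
    """Neonatal ponderal index, weight / length³ in kg/m³."""
    return np.asarray(weight_kg, float) / np.asarray(length_m, float) ** 3


def standardize_outcomes(
    cohort: DuoCohort,
    outcomes: Sequence[str] | None = None,
    log_transform: Sequence[str] = (),
) -> DuoCohort:
    """Return a copy with z-scored outcome columns (within this cohort).

    The ponderal index is derived first (kg/m³ from ``birth_weight_g`` and
    ``birth_length_cm``) where absent.  Columns in ``log_transform`` (e.g.
    skewed cord-blood analytes) are log-transformed before z-scoring; the
    default keeps the natural scale.  Missing values are preserved; a
    zero-variance outcome raises, naming the column.
    """
    data = cohort.data.copy()
    outcome_cols = list(cohort.outcome_columns)
    if (
        "ponderal_index" not in data.columns
        and "birth_weight_g" in data.columns
        and "birth_length_cm" in data.columns
    ):
        data["ponderal_index"] = ponderal_index(
            data["birth_weight_g"].to_numpy(float) / 1000.0,
            data["birth_length_cm"].to_numpy(float) / 100.0,
        )
        outcome_cols.append("ponderal_index")
    if (
        "sum_skinfolds_mm" not in data.columns
        and "triceps_skinfold_mm" in data.columns
        and "subscapular_skinfold_mm" in data.columns
    ):
        data["sum_skinfolds_mm"] = data["triceps_skinfold_mm"] + data["subscapular_skinfold_mm"]
        outcome_cols.append("sum_skinfolds_mm")

    targets = list(outcomes) if outcomes is not None else outcome_cols
    for col in targets:
        values = data[col].astype(float)
        if col in log_transform:
            values = np.log(values)
        valid = values.dropna()
        if len(valid) < 2:
            raise DegenerateInputError(f"outcome {col!r}: fewer than 2 non-missing values")
        sd = valid.std(ddof=1)
        if not sd > 0:
            raise DegenerateInputError(f"outcome {col!r}: zero variance, cannot standardize")
        data[col] = (values - valid.mean()) / sd
    return dataclasses.replace(cohort, data=data, outcome_columns=outcome_cols)


def fit_snp_model(
    cohort: DuoCohort,
    snp_id: str,
    outcome: str,
    adjust_maternal: bool = True,
) -> CohortAssoc:
    """Per-allele association of one SNP with one (standardized) outcome.

    Least-squares fit of the outcome on the child dosage, plus maternal dosage
    (when ``adjust_maternal``), sex and gestational age.  Rows with any
    missing model variable are listwise-deleted.  Returns the child-dosage
    coefficient and its SE.
    """
    cols = [outcome, f"c_{snp_id}"]
    if adjust_maternal:
        cols.append(f"m_{snp_id}")
    cols += ["sex", "gestational_age"]
    frame = cohort.data[cols].astype(float).dropna()
    n_params = len(cols)  # predictors + intercept (outcome column offsets the count)
    if len(frame) < n_params + 10:
        raise InsufficientInputError(
            f"{cohort.cohort}/{snp_id}/{outcome}: only {len(frame)} complete rows "
            f"for {n_params} parameters"
        )
    y = frame[outcome].to_numpy()
    X = sm.add_constant(frame[cols[1:]].to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError(
            f"{cohort.cohort}/{snp_id}/{outcome}: collinear or constant design "
            "(rank-deficient model matrix)"
        )
    result = sm.OLS(y, X).fit()
    return CohortAssoc(
        cohort=cohort.cohort,
        snp_id=snp_id,
        outcome=outcome,
        beta=float(result.params[1]),
        se=float(result.bse[1]),
        n_used=len(frame),
    )


def meta_across_cohorts(assocs: Sequence[CohortAssoc]) -> tuple[CohortAssoc, PooledEffect]:
    """Fixed-effects pooling of one SNP/outcome association across cohorts.

    Returns the pooled association (cohort label ``"pooled"``) together with
    the full ``PooledEffect`` carrying Cochran's Q and I² across cohorts.
    Mixed SNPs or outcomes in the input raise.
    """
    if len(assocs) < 2:
        raise InsufficientInputError("meta-analysis across cohorts requires >= 2 cohorts")
    snp_ids = {a.snp_id for a in assocs}
    outcomes = {a.outcome for a in assocs}
    if len(snp_ids) > 1 or len(outcomes) > 1:
        raise IntegrityError(
            f"mixed inputs: snp_ids={sorted(snp_ids)}, outcomes={sorted(outcomes)}"
        )
    pooled = pool_fixed([(a.beta, a.se) for a in assocs])
    assoc = CohortAssoc(
        cohort="pooled",
        snp_id=snp_ids.pop(),
        outcome=outcomes.pop(),
        beta=pooled.estimate,
        se=pooled.se,
        n_used=sum(a.n_used for a in assocs),
    )
    return assoc, pooled


def apply_exclusions(
    cohort: DuoCohort,
    min_birthweight_g: float | None = 2200.0,
    drop_multiple_births: bool = True,
    max_report_discrepancy_g: float | None = 500.0,
) -> tuple[DuoCohort, dict[str, int]]:
    """Apply the birth-record exclusion rules; returns counts per rule.

    Rules (each individually disableable with ``None``/``False``): drop
    births below ``min_birthweight_g`` (a proxy for excluding preterm births
    where gestational age is unreliable), drop multiple births, and drop duos
    whose two birth-weight reports differ by more than
    ``max_report_discrepancy_g``.  An empty result is permitted.
    """
    data = cohort.data
    keep = pd.Series(True, index=data.index)
    counts: dict[str, int] = {}
    if min_birthweight_g is not None and "birth_weight_g" in data.columns:
        rule = data["birth_weight_g"] < min_birthweight_g
        counts["low_birthweight"] = int(rule.sum())
        keep &= ~rule
    if drop_multiple_births and "multiple_birth" in data.columns:
        rule = data["multiple_birth"] == 1
        counts["multiple_birth"] = int(rule.sum())
        keep &= ~rule
    if max_report_discrepancy_g is not None and "birth_weight_g_report2" in data.columns:
        rule = (data["birth_weight_g"] - data["birth_weight_g_report2"]).abs() > max_report_discrepancy_g
        counts["report_discrepancy"] = int(rule.sum())
        keep &= ~rule
    out = dataclasses.replace(cohort, data=data.loc[keep].reset_index(drop=True))
    if out.n == 0:
        import warnings

        warnings.warn(f"cohort {cohort.cohort}: all rows excluded")
    return out, counts
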