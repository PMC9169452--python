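"""Dose-response proportionality of SNP effects via weighted linear regression.

Regresses per-SNP outcome (birth weight) effects on per-SNP exposure (adult
adiposity) effects, weighting each SNP by the precision of its outcome
estimate.  A positive slope with substantial adjusted R² indicates that
alleles with larger adult-trait effects also have proportionally larger
birth-weight effects; adjusted R² near (or below) zero indicates no
dose-dependent relationship.  Adjusted R² is reported because it is the
quantity that can legitimately go negative for a non-explanatory fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateInputError, InsufficientInputError, ValidationError

__all__ = ["DoseResponseFit", "fit_weighted_slope", "plot_dose_response"]


@dataclass(frozen=True)
class DoseResponseFit:
    """Weighted-least-squares fit of outcome betas on exposure betas."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    adj_r2: float
    pval_slope: float
    k: int


def fit_weighted_slope(
    pairs: Sequence[tuple[float, float, float]],
    weight_power: float = 2.0,
) -> DoseResponseFit:
    """Fit outcome_beta ~ intercept + slope * exposure_beta by WLS.

    Parameters
    ----------
    pairs
        ``(exposure_beta, outcome_beta, outcome_se)`` per SNP.
    weight_power
        Weights are ``outcome_se ** -weight_power``; the default 2 is
        precision weighting (equivalent to dividing both sides of the model
        by the outcome SE), 1 gives plain inverse-SE weighting for
        sensitivity analyses.

    The weighted R² uses residual and total sums of squares about the
    weighted mean; the slope p-value is two-sided from a t distribution with
    k-2 degrees of freedom.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInputError(f"weighted regression requires k >= 3 SNPs, got {k}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    se = np.array([p[2] for p in pairs], dtype=float)
    if np.any(se <= 0):
        raise ValidationError("all outcome standard errors must be > 0")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in exposure betas: slope unidentifiable")

    weights = se**-weight_power
    result = sm.WLS(y, sm.add_constant(x), weights=weights).fit()
    return DoseResponseFit(
        slope=float(result.params[1]),
        slope_se=float(result.bse[1]),
        intercept=float(result.params[0]),
        intercept_se=float(result.bse[0]),
        r2=float(result.rsquared),
        adj_r2=float(result.rsquared_adj),
        pval_slope=float(result.pvalues[1]),
        k=k,
    )


def plot_dose_response(
    pairs: Sequence[tuple[float, float, float]],
    fit: DoseResponseFit,
    path: str | Path,
    xlabel: str = "SNP effect on adult trait",
    ylabel: str = "SNP effect on birth weight",
    title: str = "",
) -> None:
    """Scatter plot of SNP effects with 95% CI bars and the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    ci = 1.96 * np.array([p[2] for p in pairs])

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.errorbar(x, y, yerr=ci, fmt="o", ms=4, capsize=2, lw=0.8, color="tab:blue")
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, color="black", lw=1.2)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    label = f"slope={fit.slope:.3g}, adj R²={fit.adj_r2:.3g}, P={fit.pval_slope:.3g}"
    ax.set_title(title or label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
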