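"""Logistic health-effect fits and Monte-Carlo operating characteristics.

Per replicate and exposure method, low birth weight is regressed on assigned
exposure by maximum-likelihood logistic regression (intercept + slope).  Over
replicates, performance is summarised on the log-odds slope scale as bias,
RMSE, average standard error (ASE), 95% coverage probability (CP), and the
true positive rate (TPR): the count of significantly positive slopes under
predicted exposure relative to the same count under true exposure.

Bias, RMSE, and ASE are multiplied by 100 for display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["FitResult", "PerformanceSummary", "fit_health_model",
           "summarize_performance", "compute_tpr"]

REPORT_SCALE = 100.0


@dataclass(frozen=True)
class FitResult:
    """One logistic fit of outcome on exposure."""

    slope: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool

    @property
    def rr(self) -> float:
        return math.exp(self.slope)

    @property
    def significant_positive(self) -> bool:
        return self.converged and self.slope > 0 and self.p_value < 0.05


@dataclass(frozen=True)
class PerformanceSummary:
    """Operating characteristics of one method x scenario cell."""

    method: str
    scenario: str
    mean_rr: float
    bias: float       # on the slope scale
    rmse: float
    ase: float
    cp: float
    tpr: float | None
    n_replicates: int
    n_nonconverged: int = 0
    scale_factor: float = REPORT_SCALE

    def to_row(self) -> dict:
        """Row matching the reporting layout (bias/RMSE/ASE x100)."""
        return {
            "scenario": self.scenario,
            "method": self.method,
            "mean_rr": self.mean_rr,
            "bias_x100": self.bias * self.scale_factor,
            "rmse_x100": self.rmse * self.scale_factor,
            "ase_x100": self.ase * self.scale_factor,
            "cp": self.cp,
            "tpr": self.tpr,
            "n_replicates": self.n_replicates,
            "n_nonconverged": self.n_nonconverged,
        }


def fit_health_model(exposure: np.ndarray, outcomes: np.ndarray) -> FitResult:
    """Maximum-likelihood logistic regression of status on exposure.

    Separation or non-convergence yields a flagged result that summaries
    exclude; constant exposure is a caller error.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("exposure is constant; the slope is not identified")
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False)) and np.all(
            np.isfinite(res.bse)
        )
    except Exception:
        return FitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    slope = float(res.params[1])
    se = float(res.bse[1])
    z = 1.959963984540054  # Phi^{-1}(0.975)
    return FitResult(
        slope=slope,
        se=se,
        ci_low=slope - z * se,
        ci_high=slope + z * se,
        p_value=float(res.pvalues[1]),
        converged=converged and se > 0,
    )


def summarize_performance(
    fits: list[FitResult],
    true_beta: float,
    method: str = "",
    scenario: str = "",
    tpr: float | None = None,
) -> PerformanceSummary:
    """Aggregate converged fits into bias/RMSE/ASE/CP (slope scale)."""
    if not fits:
        raise ValueError("no fits to summarise")
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to summarise")
    slopes = np.array([f.slope for f in ok])
    ses = np.array([f.se for f in ok])
    covered = np.array([f.ci_low <= true_beta <= f.ci_high for f in ok])
    return PerformanceSummary(
        method=method,
        scenario=scenario,
        mean_rr=float(np.mean(np.exp(slopes))),
        bias=float(slopes.mean() - true_beta),
        rmse=float(np.sqrt(np.mean((slopes - true_beta) ** 2))),
        ase=float(ses.mean()),
        cp=float(covered.mean()),
        tpr=tpr,
        n_replicates=len(ok),
        n_nonconverged=len(fits) - len(ok),
    )


def compute_tpr(fits_predicted: list[FitResult], fits_true: list[FitResult],
                alpha: float = 0.05) -> float:
    """Significantly-positive count under predicted vs under true exposure.

    NaN (with no ratio defined) when no replicate is significant under true
    exposure.
    """
    if len(fits_predicted) != len(fits_true):
        raise ValueError("replicate lists must be paired")

    def count(fits):
        return sum(1 for f in fits
                   if f.converged and f.slope > 0 and f.p_value < alpha)

    denom = count(fits_true)
    if denom == 0:
        return float("nan")
    return count(fits_predicted) / denom
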