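"""Binary low-birth-weight outcomes from true exposure via an inverse-logit model.

Each mother's LBW status is Bernoulli with

    logit P(Y_i = 1) = alpha + beta * x_i,

where ``beta = ln(true RR)`` per µg/m³ of PM10 and ``alpha`` is calibrated so
the average event probability over mothers equals the target baseline
prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = ["HealthParams", "calibrate_intercept", "generate_outcomes"]


@dataclass(frozen=True)
class HealthParams:
    """True health-effect parameters of the outcome model."""

    true_rr: float = 1.0033  # relative risk per 1 µg/m³
    baseline_prevalence: float = 0.05

    def __post_init__(self) -> None:
        if self.true_rr <= 0:
            raise ValueError("true_rr must be positive")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")

    @property
    def true_beta(self) -> float:
        return math.log(self.true_rr)


def calibrate_intercept(true_exposure: np.ndarray, params: HealthParams, tol: float = 1e-10) -> float:
    """Solve for the intercept giving the target mean event probability.

    The mean of expit(alpha + beta x_i) is strictly increasing in alpha, so
    Brent root-finding on a wide bracket is exact to ``tol``.
    """
    x = np.asarray(true_exposure, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("exposures must be finite")
    beta = params.true_beta
    target = params.baseline_prevalence

    def gap(alpha: float) -> float:
        return expit(alpha + beta * x).mean() - target

    centre = logit(target) - beta * x.mean()
    half = abs(beta) * (x.max() - x.min()) + 10.0
    lo, hi = centre - half, centre + half
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("no intercept root in bracket")
    return float(brentq(gap, lo, hi, xtol=tol))


def generate_outcomes(
    true_exposure: np.ndarray,
    params: HealthParams,
    replicate_seed,
    intercept: float | None = None,
) -> np.ndarray:
    """Draw independent Bernoulli LBW statuses, one per mother."""
    x = np.asarray(true_exposure, dtype=float)
    if intercept is None:
        intercept = calibrate_intercept(x, params)
    p = expit(intercept + params.true_beta * x)
    rng = np.random.default_rng(replicate_seed)
    return (rng.random(len(x)) < p).astype(np.int8)
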