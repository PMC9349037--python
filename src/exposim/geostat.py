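"""Variogram estimation and model-based exposure prediction (LUR, universal kriging).

Each simulation replicate re-estimates the spatial structure of PM10 from the
simulated monitor values alone, exactly as a prediction model built on a real
monitoring network would: detrend by ordinary least squares on the geographic
covariates, compute the classical (Matheron) empirical semivariogram of the
residuals, fit an exponential variogram by weighted least squares, and then
predict at target locations by universal kriging with the covariates as
drift.  Land-use regression (LUR) is the same drift regression without the
spatial-correlation term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist

from .exposure import exponential_correlation

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "LurModel",
    "empirical_variogram",
    "exponential_semivariance",
    "fit_variogram",
    "fit_lur",
    "krige_universal",
]


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned Matheron semivariance estimates."""

    bin_centres: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray
    max_distance: float

    @property
    def nonempty(self) -> np.ndarray:
        return self.pair_counts > 0


@dataclass(frozen=True)
class VariogramModel:
    """A fitted exponential variogram (same range convention as the simulator)."""

    nugget: float
    partial_sill: float
    range_m: float
    family: str = "exponential"
    convention: str = "practical"
    fallback: bool = False  # True when the WLS optimiser failed and moment
    #                         estimates were substituted

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def semivariance(self, h: np.ndarray) -> np.ndarray:
        return exponential_semivariance(h, self.nugget, self.partial_sill,
                                        self.range_m, self.convention)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Covariance between distinct points at separation h (no nugget)."""
        return self.partial_sill * exponential_correlation(h, self.range_m, self.convention)


def exponential_semivariance(h, nugget, partial_sill, range_m, convention="practical"):
    h = np.asarray(h, dtype=float)
    gamma = nugget + partial_sill * (1.0 - exponential_correlation(h, range_m, convention))
    return np.where(h > 0, gamma, 0.0)


def empirical_variogram(
    points: np.ndarray,
    values: np.ndarray,
    n_bins: int = 8,
    max_distance: float | None = None,
    bin_edges: str = "uniform",
) -> EmpiricalVariogram:
    """Classical Matheron estimator on binned pair distances.

    For each bin, half the mean squared difference over all point pairs whose
    separation falls in the bin; pairs beyond ``max_distance`` (default: half
    the maximum pairwise distance) are excluded.  ``bin_edges="uniform"``
    gives equal-width bins (the right default for sparse monitor networks);
    ``"geometric"`` concentrates bins at short distances (starting at 1% of
    ``max_distance``), which identifies the nugget better on dense data;
    ``"quantile"`` places edges at pair-distance quantiles so no bin is empty
    (the robust choice for very small networks).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least two points")
    d = pdist(points)
    if max_distance is None:
        max_distance = d.max() / 2.0
    keep = d <= max_distance
    if not keep.any():
        raise ValueError("all point pairs are beyond max_distance")
    sq = pdist(values[:, None], metric="sqeuclidean")[keep] / 2.0
    db = d[keep]
    if bin_edges == "uniform":
        edges = np.linspace(0.0, max_distance, n_bins + 1)
    elif bin_edges == "geometric":
        edges = np.concatenate([[0.0],
                                np.geomspace(max_distance / 100.0, max_distance, n_bins)])
    elif bin_edges == "quantile":
        # edges at pair-distance quantiles: every bin non-empty by construction
        qs = np.quantile(db, np.linspace(0.0, 1.0, n_bins + 1))
        edges = np.concatenate([[0.0], qs[1:-1], [max_distance]])
    else:
        raise ValueError(f"unknown bin_edges {bin_edges!r}")
    which = np.clip(np.digitize(db, edges[1:], right=True), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sq, minlength=n_bins)
    dsum = np.bincount(which, weights=db, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # abscissa: mean pair distance per bin (not the geometric centre) — the
    # convention of gstat/geoR; matters for skewed within-bin distributions
    centres = (edges[:-1] + edges[1:]) / 2.0
    centres = np.where(counts > 0, dsum / np.maximum(counts, 1), centres)
    return EmpiricalVariogram(centres, gamma, counts, max_distance)


def _wls_objective(theta, h, gamma, counts):
    nug, psill, rng_m = theta
    model = exponential_semivariance(h, nug, psill, rng_m)
    model = np.maximum(model, 1e-12)
    return float(np.sum(counts * (gamma - model) ** 2 / model**2))


def fit_variogram(
    emp: EmpiricalVariogram,
    bounds: tuple | None = None,
    convention: str = "practical",
) -> VariogramModel:
    """Fit the exponential model by weighted least squares (Cressie weights).

    The objective sum_j N_j (gamma_j - gamma(h_j; theta))^2 / gamma(h_j)^2 is
    minimised from a deterministic 5x5x5 multi-start grid over (nugget,
    partial sill, range); the best grid points are refined by L-BFGS-B.  On
    optimiser failure, moment estimates are substituted and flagged.
    """
    mask = emp.nonempty
    h = emp.bin_centres[mask]
    gamma = emp.semivariances[mask]
    counts = emp.pair_counts[mask]
    if mask.sum() < 3:
        raise ValueError("need at least three non-empty bins")

    sill0 = max(gamma.max(), 1e-12)
    if bounds is None:
        bounds = ((0.0, 3.0 * sill0), (1e-12, 5.0 * sill0), (h[0] / 10.0, 20.0 * emp.max_distance))

    nug_grid = np.linspace(0.0, sill0, 5)
    psill_grid = np.array([0.05, 0.4, 0.8, 1.2, 1.6]) * sill0
    rng_grid = np.geomspace(max(h[0], 1e-6), 3.0 * emp.max_distance, 5)
    starts = [(a, b, c) for a in nug_grid for b in psill_grid for c in rng_grid]
    scores = np.array([_wls_objective(t, h, gamma, counts) for t in starts])
    order = np.argsort(scores)

    best, best_val = None, np.inf
    for i in order[:3]:
        try:
            res = minimize(_wls_objective, starts[i], args=(h, gamma, counts),
                           method="L-BFGS-B", bounds=bounds)
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if np.all(np.isfinite(res.x)) and res.fun < best_val:
            best, best_val = res.x, res.fun
    if best is None:  # pragma: no cover
        return VariogramModel(
            nugget=float(gamma[0]),
            partial_sill=float(max(np.var(gamma), 1e-12)),
            range_m=emp.max_distance / 2.0,
            convention=convention,
            fallback=True,
        )
    return VariogramModel(nugget=float(best[0]), partial_sill=float(best[1]),
                          range_m=float(best[2]), convention=convention)


@dataclass(frozen=True)
class LurModel:
    """Pointwise regression of monitor concentrations on geographic covariates."""

    intercept: float
    coefficients: np.ndarray
    residual_variance: float

    def predict(self, covariates: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(covariates, dtype=float) @ self.coefficients


def fit_lur(monitor_values: np.ndarray, monitor_covariates: np.ndarray) -> LurModel:
    """Ordinary least squares of monitor values on the covariates."""
    y = np.asarray(monitor_values, dtype=float)
    X = np.asarray(monitor_covariates, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more monitors ({n}) than covariates plus intercept ({p + 1})")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # identify offending columns by incremental rank
        bad = []
        for j in range(design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
                bad.append(j - 1)  # covariate index (0-based, excluding intercept)
        raise ValueError(f"rank-deficient design; collinear covariate columns: {bad}")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return LurModel(
        intercept=float(coef[0]),
        coefficients=coef[1:],
        residual_variance=float(resid @ resid / (n - p - 1)),
    )


def krige_universal(
    monitor_points: np.ndarray,
    monitor_values: np.ndarray,
    monitor_covariates: np.ndarray,
    vgm: VariogramModel,
    target_points: np.ndarray,
    target_covariates: np.ndarray,
    return_variance: bool = False,
    jitter: float = 1e-10,
):
    """Universal-kriging predictions (and variances) at target points.

    Solves, per target s0 with drift f(s) = [1, x(s)]:

        [ C   F ] [lambda]   [ c0 ]
        [ F'  0 ] [  mu  ] = [ f0 ]

    where C is the monitor covariance (sill on the diagonal), c0 the
    monitor-target covariances (no nugget: the target's micro-scale noise is
    unpredictable).  With zero nugget the predictor interpolates the monitors
    exactly.  The kriging variance is sill - lambda'c0 - mu'f0, clipped at 0.
    """
    xm = np.asarray(monitor_points, dtype=float)
    y = np.asarray(monitor_values, dtype=float)
    Xm = np.asarray(monitor_covariates, dtype=float)
    xt = np.asarray(target_points, dtype=float)
    Xt = np.asarray(target_covariates, dtype=float)
    n, p = Xm.shape

    C = vgm.covariance(cdist(xm, xm))
    np.fill_diagonal(C, vgm.sill)
    F = np.column_stack([np.ones(n), Xm])
    q = p + 1
    K = np.zeros((n + q, n + q))
    K[:n, :n] = C
    K[:n, n:] = F
    K[n:, :n] = F.T

    rhs = np.zeros((n + q, len(xt)))
    rhs[:n] = vgm.covariance(cdist(xm, xt))
    rhs[n:] = np.column_stack([np.ones(len(xt)), Xt]).T

    try:
        lu = lu_factor(K)
    except Exception:
        K[:n, :n] += jitter * max(vgm.sill, 1.0) * np.eye(n)
        lu = lu_factor(K)  # raises if still singular
    W = lu_solve(lu, rhs)

    pred = y @ W[:n]
    if not return_variance:
        return pred
    var = vgm.sill - np.einsum("ij,ij->j", rhs, W)
    return pred, np.maximum(var, 0.0)
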