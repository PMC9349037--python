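"""Per-mother exposure assignment under nine prediction methods.

Complete-address methods (each mother's own coordinates are used):
NM (nearest monitor), IDWA (inverse-squared-distance weighted average of the
background monitors), LUR and UK predictions at the home.

District-address methods (only the district of residence is known): AA
(district mean of background monitors — with one monitor per district, the
single-site value), UKD (UK prediction at the district governmental office),
and district averages of UK predictions at neighbourhood centres (UKNA),
census-tract centroids (UKCA) and 1-km grid centroids (UKGA).

TE is the mother's simulated true exposure and anchors all comparisons.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "METHOD_CODES",
    "ADDRESS_CONDITION",
    "assign_nearest_monitor",
    "assign_idwa",
    "assign_area_average",
    "assign_uk_point",
    "aggregate_district_mean",
]

METHOD_CODES = ("TE", "NM", "IDWA", "LUR", "UK", "AA", "UKD", "UKNA", "UKCA", "UKGA")

ADDRESS_CONDITION = {
    "TE": "truth",
    "NM": "complete", "IDWA": "complete", "LUR": "complete", "UK": "complete",
    "AA": "district", "UKD": "district", "UKNA": "district",
    "UKCA": "district", "UKGA": "district",
}


def assign_nearest_monitor(mother_xy, monitor_xy, monitor_values):
    """Each mother gets her Euclidean-nearest monitor's value (ties: lowest id)."""
    d = cdist(np.asarray(mother_xy, float), np.asarray(monitor_xy, float))
    return np.asarray(monitor_values, float)[np.argmin(d, axis=1)]


def assign_idwa(mother_xy, monitor_xy, monitor_values, power: float = 2.0,
                coincidence_tol: float = 1e-9):
    """Inverse-distance-power weighted average over all monitors.

    A mother within ``coincidence_tol`` metres of a monitor receives that
    monitor's value exactly (lowest monitor id on multiple coincidences).
    """
    y = np.asarray(monitor_values, float)
    d = cdist(np.asarray(mother_xy, float), np.asarray(monitor_xy, float))
    coincident = d < coincidence_tol
    hit = coincident.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.where(d > 0, d, np.inf) ** power
    out = (w @ y) / w.sum(axis=1)
    if hit.any():
        out[hit] = y[np.argmax(coincident[hit], axis=1)]
    return out


def _district_means(values, districts, n_districts, kind: str):
    values = np.asarray(values, float)
    districts = np.asarray(districts, int)
    sums = np.bincount(districts, weights=values, minlength=n_districts)
    counts = np.bincount(districts, minlength=n_districts)
    means = np.full(n_districts, np.nan)
    has = counts > 0
    means[has] = sums[has] / counts[has]
    return means, has


def assign_area_average(mother_districts, monitor_districts, monitor_values,
                        n_districts: int):
    """District mean of background-monitor values, broadcast to its mothers."""
    means, has = _district_means(monitor_values, monitor_districts, n_districts, "monitor")
    mother_districts = np.asarray(mother_districts, int)
    missing = np.setdiff1d(np.unique(mother_districts), np.flatnonzero(has))
    if missing.size:
        raise ValueError(f"districts with mothers but no monitor: {missing.tolist()}")
    return means[mother_districts]


def assign_uk_point(mother_districts, office_predictions, office_districts=None):
    """Broadcast the district office's UK prediction to the district's mothers.

    With ``office_districts`` omitted, office ``d`` is assumed to serve
    district ``d`` (the construction used throughout).
    """
    office_predictions = np.asarray(office_predictions, float)
    mother_districts = np.asarray(mother_districts, int)
    if office_districts is not None:
        order = np.argsort(np.asarray(office_districts, int))
        office_predictions = office_predictions[order]
    if mother_districts.max() >= len(office_predictions):
        raise ValueError("missing office prediction for some district")
    return office_predictions[mother_districts]


def aggregate_district_mean(point_predictions, point_districts, mother_districts,
                            n_districts: int):
    """Unweighted district mean of point predictions, broadcast to mothers.

    Used with neighbourhood centres (UKNA), tract centroids (UKCA) and grid
    centroids (UKGA) as the aggregation point sets.
    """
    means, has = _district_means(point_predictions, point_districts, n_districts, "point")
    mother_districts = np.asarray(mother_districts, int)
    missing = np.setdiff1d(np.unique(mother_districts), np.flatnonzero(has))
    if missing.size:
        raise ValueError(f"districts with mothers but no aggregation point: {missing.tolist()}")
    return means[mother_districts]
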