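"""Synthetic study region: districts, neighbourhoods, tracts, monitors, mothers.

The region is a square of side ``region_extent_km`` tessellated into
``n_districts`` rectangular districts (a near-square grid), each district
tessellated into its share of ``n_neighbourhoods``.  Census-tract centroids
scatter uniformly within neighbourhoods; mothers' homes are tract centroids
sampled with probability proportional to their neighbourhood's birth weight,
mirroring how residential addresses in birth-certificate data resolve only to
administrative units.  One urban-background monitor and one governmental
office sit in every district; roadside monitors fall uniformly over the
region; 1-km-style grid centroids form a regular lattice.

All coordinates are planar metres with the origin at the region corner, and
all point sets index into one table of unique coordinates so that any two
points sharing a location share covariate values and, later, the same
realisation of the simulated exposure surface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "RegionConfig",
    "GeoCovariates",
    "StudyRegion",
    "ROLES",
    "DESK_SCALE",
    "FULL_SCALE",
    "build_geography",
    "sample_mother_homes",
    "generate_covariates",
    "region_to_csv",
    "region_from_csv",
    "region_to_geojson",
]

ROLES = (
    "monitor_background",
    "monitor_roadside",
    "district_office",
    "neighbourhood_centre",
    "tract_centroid",
    "grid_centroid",
    "mother_home",
)


class ConfigurationError(ValueError):
    """Raised when a region configuration cannot be realised."""


@dataclass(frozen=True)
class RegionConfig:
    """Counts and extent defining a synthetic study region.

    Defaults are the desk scale used for day-to-day runs; ``FULL_SCALE``
    carries the full Seoul-like counts (25 districts, 422 neighbourhoods,
    16,230 tracts, 46,007 mothers, 25+12 monitors, 610 grid centroids).
    """

    n_districts: int = 5
    n_neighbourhoods: int = 20
    n_tracts: int = 800
    n_background_monitors: int | None = None  # defaults to n_districts
    n_roadside_monitors: int = 3
    n_grid_points: int = 100
    n_mothers: int = 2000
    region_extent_km: float = 25.0
    covariate_count: int = 5
    mother_replace: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_monitors is None:
            object.__setattr__(self, "n_background_monitors", self.n_districts)
        counts = (
            self.n_districts,
            self.n_neighbourhoods,
            self.n_tracts,
            self.n_background_monitors,
            self.n_roadside_monitors,
            self.n_grid_points,
            self.n_mothers,
            self.covariate_count,
        )
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all counts must be positive")
        if self.region_extent_km <= 0:
            raise ConfigurationError("region_extent_km must be positive")
        if self.n_background_monitors != self.n_districts:
            raise ConfigurationError(
                "one urban-background monitor per district is required "
                f"(got {self.n_background_monitors} monitors, {self.n_districts} districts)"
            )
        if self.n_neighbourhoods < self.n_districts:
            raise ConfigurationError("need at least one neighbourhood per district")
        if self.n_tracts < self.n_neighbourhoods:
            raise ConfigurationError("need at least one tract centroid per neighbourhood")

    @property
    def extent_m(self) -> float:
        return self.region_extent_km * 1000.0

    def to_dict(self) -> dict:
        return {
            "n_districts": self.n_districts,
            "n_neighbourhoods": self.n_neighbourhoods,
            "n_tracts": self.n_tracts,
            "n_background_monitors": self.n_background_monitors,
            "n_roadside_monitors": self.n_roadside_monitors,
            "n_grid_points": self.n_grid_points,
            "n_mothers": self.n_mothers,
            "region_extent_km": self.region_extent_km,
            "covariate_count": self.covariate_count,
            "mother_replace": self.mother_replace,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegionConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


DESK_SCALE = RegionConfig()
FULL_SCALE = RegionConfig(
    n_districts=25,
    n_neighbourhoods=422,
    n_tracts=16230,
    n_background_monitors=25,
    n_roadside_monitors=12,
    n_grid_points=610,
    n_mothers=46007,
    region_extent_km=25.0,
)


@dataclass(frozen=True)
class GeoCovariates:
    """Standardised geographic covariates evaluated at the unique coordinates.

    Columns are smooth spatial surfaces plus a small point-level noise term,
    standardised to mean 0 / variance 1 over tract centroids.  They stand in
    for land-use variables (road density, population, elevation, ...) that are
    spatially structured but not collinear.
    """

    values: np.ndarray  # (n_unique, covariate_count)
    names: tuple[str, ...]


@dataclass
class StudyRegion:
    """The full synthetic spatial frame for one study.

    ``points`` maps each role in :data:`ROLES` to a DataFrame with columns
    ``x, y, district_id, neighbourhood_id, u_idx`` where ``u_idx`` indexes
    into ``coords`` / ``covariates.values``.
    """

    config: RegionConfig
    points: dict[str, pd.DataFrame]
    coords: np.ndarray  # (n_unique, 2) unique coordinates, metres
    covariates: GeoCovariates
    birth_weights: np.ndarray  # one nonnegative weight per neighbourhood
    district_rects: np.ndarray  # (n_districts, 4): x0, y0, x1, y1
    neighbourhood_rects: np.ndarray  # (n_neighbourhoods, 4)
    neighbourhood_district: np.ndarray  # parent district of each neighbourhood

    @property
    def n_districts(self) -> int:
        return self.config.n_districts

    def covariates_for(self, role: str) -> np.ndarray:
        """Covariate matrix aligned with the rows of ``points[role]``."""
        return self.covariates.values[self.points[role]["u_idx"].to_numpy()]

    def coords_for(self, role: str) -> np.ndarray:
        pts = self.points[role]
        return np.column_stack([pts["x"].to_numpy(), pts["y"].to_numpy()])


# ---------------------------------------------------------------------------
# tessellation helpers

def _split_counts(n: int, k: int) -> list[int]:
    """Distribute n items over k bins as evenly as possible (first bins larger)."""
    base, extra = divmod(n, k)
    return [base + 1 if i < extra else base for i in range(k)]


def _tessellate(n_cells: int, x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    """Partition a rectangle into ``n_cells`` rectangles on a near-square grid.

    Rows are horizontal strips of equal height; each row is split into its
    share of cells of equal width.  Returns (n_cells, 4) rects in row-major
    order.  The cells tile the rectangle exactly.
    """
    rows = max(1, round(math.sqrt(n_cells)))
    per_row = _split_counts(n_cells, rows)
    height = (y1 - y0) / rows
    rects = []
    for r, ncols in enumerate(per_row):
        ry0 = y0 + r * height
        width = (x1 - x0) / ncols
        for c in range(ncols):
            rects.append((x0 + c * width, ry0, x0 + (c + 1) * width, ry0 + height))
    return np.asarray(rects)


def _rect_contains_index(rects: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Map each point to the index of the rect containing it (rects tile a box)."""
    idx = np.full(len(xy), -1, dtype=int)
    for i, (rx0, ry0, rx1, ry1) in enumerate(rects):
        inside = (
            (xy[:, 0] >= rx0) & (xy[:, 0] < rx1 + 1e-9)
            & (xy[:, 1] >= ry0) & (xy[:, 1] < ry1 + 1e-9)
            & (idx < 0)
        )
        idx[inside] = i
    return idx


def _uniform_in_rect(rng: np.random.Generator, rect: np.ndarray, n: int) -> np.ndarray:
    x = rng.uniform(rect[0], rect[2], n)
    y = rng.uniform(rect[1], rect[3], n)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# covariate surfaces

class _CovariateSurface:
    """A random spatial surface: a superposition of Gaussian radial bumps.

    Bump widths are log-uniform between 2% and 30% of the region extent, so
    each surface mixes sub-district texture (land-use variables such as road
    density vary within administrative districts) with a regional gradient
    (district averages still differ across the city).
    """

    def __init__(self, rng: np.random.Generator, extent: float, n_bumps: int = 40,
                 width_range: tuple[float, float] = (0.02, 0.30)):
        self.centres = rng.uniform(0.0, extent, size=(n_bumps, 2))
        self.widths = np.exp(rng.uniform(np.log(width_range[0] * extent),
                                         np.log(width_range[1] * extent),
                                         size=n_bumps))
        self.amps = rng.standard_normal(n_bumps)

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        d2 = ((xy[:, None, :] - self.centres[None, :, :]) ** 2).sum(axis=2)
        s = (self.amps * np.exp(-d2 / (2.0 * self.widths**2))).sum(axis=1)
        sd = s.std()
        return (s - s.mean()) / (sd if sd > 0 else 1.0)


#: loading of each covariate on the shared latent surface; real land-use
#: variables correlate through common urbanicity, so columns share structure
_SHARED_LOADINGS = (0.8, 0.7, 0.6, 0.5, 0.4)


def generate_covariates(
    coords: np.ndarray,
    tract_u_idx: np.ndarray,
    config: RegionConfig,
    noise_sd: float = 0.1,
) -> GeoCovariates:
    """Generate standardised covariate columns at the unique coordinates.

    Covariate j is sqrt(rho_j) * shared latent surface + sqrt(1 - rho_j) *
    its own surface + N(0, noise_sd) point-level noise, then standardised to
    mean 0 / variance 1 over tract centroids so the exposure mean structure
    downstream is expressed per covariate SD.  The shared latent component
    induces the mutual correlation (pairwise r around 0.4-0.8) typical of
    geographic predictor sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FA]))
    shared = _CovariateSurface(rng, config.extent_m)(coords)
    cols = []
    for j in range(config.covariate_count):
        rho = _SHARED_LOADINGS[j % len(_SHARED_LOADINGS)]
        own = _CovariateSurface(rng, config.extent_m)(coords)
        smooth = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        cols.append(smooth + rng.normal(0.0, noise_sd, size=len(coords)))
    values = np.column_stack(cols)
    tract_rows = values[tract_u_idx]
    mu = tract_rows.mean(axis=0)
    sigma = tract_rows.std(axis=0)
    sigma[sigma == 0] = 1.0
    values = (values - mu) / sigma
    names = tuple(f"gv{i + 1}" for i in range(config.covariate_count))
    return GeoCovariates(values=values, names=names)


# ---------------------------------------------------------------------------
# main builders

def build_geography(config: RegionConfig) -> StudyRegion:
    """Build the full synthetic study region, deterministically for a seed.

    Districts tessellate the square extent; neighbourhoods nest in districts;
    tract centroids scatter within neighbourhoods; mothers' homes are tract
    centroids sampled with birth-count weights and fixed thereafter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E0]))
    L = config.extent_m

    district_rects = _tessellate(config.n_districts, 0.0, 0.0, L, L)

    # neighbourhoods nested in districts
    neigh_per_district = _split_counts(config.n_neighbourhoods, config.n_districts)
    neigh_rects, neigh_district = [], []
    for d, k in enumerate(neigh_per_district):
        sub = _tessellate(k, *district_rects[d])
        neigh_rects.extend(sub)
        neigh_district.extend([d] * k)
    neigh_rects = np.asarray(neigh_rects)
    neigh_district = np.asarray(neigh_district)

    # birth-count weights per neighbourhood (synthetic; Gamma gives realistic skew)
    birth_weights = rng.gamma(shape=2.0, scale=1.0, size=config.n_neighbourhoods)

    # tract centroids scattered within neighbourhoods; census tracts are
    # near-equal-population units, so their density follows births: allocate
    # counts proportional to the neighbourhood birth weight (at least one)
    tracts_per_neigh = 1 + _largest_remainder(
        (config.n_tracts - config.n_neighbourhoods)
        * birth_weights / birth_weights.sum()
    )
    txy, t_neigh = [], []
    for nb, k in enumerate(tracts_per_neigh):
        txy.append(_uniform_in_rect(rng, neigh_rects[nb], k))
        t_neigh.extend([nb] * k)
    txy = np.vstack(txy)
    t_neigh = np.asarray(t_neigh)
    t_district = neigh_district[t_neigh]

    # one background monitor per district, near the district centre; the
    # governmental office sits in the district's most populated (highest
    # birth-weight) neighbourhood, as civic centres do
    bg_xy, office_xy = [], []
    for d, rect in enumerate(district_rects):
        cx, cy = (rect[0] + rect[2]) / 2, (rect[1] + rect[3]) / 2
        w, h = rect[2] - rect[0], rect[3] - rect[1]
        jitter = rng.uniform(-0.15, 0.15, 2)
        bg_xy.append([cx + jitter[0] * w, cy + jitter[1] * h])
        nbs = np.flatnonzero(neigh_district == d)
        top = nbs[np.argmax(birth_weights[nbs])]
        office_xy.append(_uniform_in_rect(rng, neigh_rects[top], 1)[0])
    bg_xy = np.asarray(bg_xy)
    office_xy = np.asarray(office_xy)

    road_xy = np.column_stack([rng.uniform(0, L, config.n_roadside_monitors),
                               rng.uniform(0, L, config.n_roadside_monitors)])

    # regular lattice of grid centroids
    k = math.ceil(math.sqrt(config.n_grid_points))
    g = (np.arange(k) + 0.5) * L / k
    gx, gy = np.meshgrid(g, g)
    grid_xy = np.column_stack([gx.ravel(), gy.ravel()])[: config.n_grid_points]

    neigh_centres = np.column_stack([
        (neigh_rects[:, 0] + neigh_rects[:, 2]) / 2,
        (neigh_rects[:, 1] + neigh_rects[:, 3]) / 2,
    ])

    def _frame(xy, district_id, neighbourhood_id=None):
        return pd.DataFrame({
            "x": xy[:, 0],
            "y": xy[:, 1],
            "district_id": np.asarray(district_id, dtype=int),
            "neighbourhood_id": (
                np.full(len(xy), -1, dtype=int)
                if neighbourhood_id is None
                else np.asarray(neighbourhood_id, dtype=int)
            ),
        })

    points = {
        "monitor_background": _frame(bg_xy, np.arange(config.n_districts)),
        "monitor_roadside": _frame(road_xy, _rect_contains_index(district_rects, road_xy)),
        "district_office": _frame(office_xy, np.arange(config.n_districts)),
        "neighbourhood_centre": _frame(neigh_centres, neigh_district,
                                       np.arange(config.n_neighbourhoods)),
        "tract_centroid": _frame(txy, t_district, t_neigh),
        "grid_centroid": _frame(grid_xy, _rect_contains_index(district_rects, grid_xy)),
    }

    # unique-coordinate table: every point set indexes into it
    base_order = ["tract_centroid", "monitor_background", "monitor_roadside",
                  "district_office", "neighbourhood_centre", "grid_centroid"]
    all_xy = np.vstack([points[r][["x", "y"]].to_numpy() for r in base_order])
    coords, inverse = np.unique(all_xy, axis=0, return_inverse=True)
    offset = 0
    for role in base_order:
        n = len(points[role])
        points[role]["u_idx"] = inverse[offset: offset + n]
        offset += n

    covariates = generate_covariates(
        coords, points["tract_centroid"]["u_idx"].to_numpy(), config
    )

    region = StudyRegion(
        config=config,
        points=points,
        coords=coords,
        covariates=covariates,
        birth_weights=birth_weights,
        district_rects=district_rects,
        neighbourhood_rects=neigh_rects,
        neighbourhood_district=neigh_district,
    )

    # mothers: per-district demand proportional to district birth weight
    district_weight = np.zeros(config.n_districts)
    np.add.at(district_weight, neigh_district, birth_weights)
    per_district = _largest_remainder(
        config.n_mothers * district_weight / district_weight.sum()
    )
    region.points["mother_home"] = sample_mother_homes(
        region, per_district, rng=rng, replace=config.mother_replace
    )
    return region


def _largest_remainder(shares: np.ndarray) -> np.ndarray:
    """Round nonnegative shares to integers preserving the total."""
    total = int(round(shares.sum()))
    floors = np.floor(shares).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(shares - floors))
    floors[order[:short]] += 1
    return floors


def sample_mother_homes(
    region: StudyRegion,
    per_district_counts: Sequence[int] | np.ndarray,
    rng: np.random.Generator | None = None,
    replace: bool = True,
) -> pd.DataFrame:
    """Sample mothers' homes among tract centroids, weighted by births.

    Within each district, a tract centroid's sampling probability is
    proportional to its neighbourhood's birth weight.  The returned point set
    is fixed across simulation replicates (homes do not move).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([region.config.seed, 0x303]))
    per_district_counts = np.asarray(per_district_counts, dtype=int)
    if len(per_district_counts) != region.n_districts:
        raise ConfigurationError("per_district_counts must have one entry per district")

    tracts = region.points["tract_centroid"]
    t_district = tracts["district_id"].to_numpy()
    t_weight = region.birth_weights[tracts["neighbourhood_id"].to_numpy()]

    chosen = []
    for d, demand in enumerate(per_district_counts):
        if demand == 0:
            continue
        rows = np.flatnonzero(t_district == d)
        w = t_weight[rows]
        if w.sum() <= 0:
            raise ConfigurationError(f"district {d} has zero total birth weight but demand {demand}")
        if not replace:
            pos = rows[w > 0]
            if demand > len(pos):
                raise ConfigurationError(
                    f"district {d}: demand {demand} exceeds {len(pos)} weighted tract centroids "
                    "(sampling without replacement)"
                )
            rows, w = pos, w[w > 0]
        chosen.append(rng.choice(rows, size=demand, replace=replace, p=w / w.sum()))
    chosen = np.concatenate(chosen)
    mothers = tracts.iloc[chosen].reset_index(drop=True)
    return mothers


# ---------------------------------------------------------------------------
# I/O

def region_to_csv(region: StudyRegion, path: str | Path) -> None:
    """Write every point set as one flat CSV (x, y, role, district, neighbourhood)."""
    frames = []
    for role, pts in region.points.items():
        f = pts[["x", "y", "district_id", "neighbourhood_id"]].copy()
        f.insert(2, "role", role)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def region_from_csv(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read the flat point-set CSV back into per-role DataFrames."""
    df = pd.read_csv(path)
    return {role: sub.drop(columns="role").reset_index(drop=True)
            for role, sub in df.groupby("role", sort=False)}


def region_to_geojson(region: StudyRegion, path: str | Path) -> None:
    """Write all point sets as a GeoJSON FeatureCollection of Points."""
    features = []
    for role, pts in region.points.items():
        for row in pts.itertuples(index=False):
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
                "properties": {
                    "role": role,
                    "district_id": int(row.district_id),
                    "neighbourhood_id": int(row.neighbourhood_id),
                },
            })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
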