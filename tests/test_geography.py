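"""Structure, determinism, and sampling behaviour of the synthetic region."""

import numpy as np
import pandas as pd
import pytest

from exposim import ConfigurationError, RegionConfig, build_geography, sample_mother_homes
from exposim.geography import (FULL_SCALE, _largest_remainder, _split_counts,
                               region_from_csv, region_to_csv, region_to_geojson)


def test_point_set_sizes_match_config(small_region, small_config):
    sizes = {role: len(pts) for role, pts in small_region.points.items()}
    assert sizes == {
        "monitor_background": small_config.n_background_monitors,
        "monitor_roadside": small_config.n_roadside_monitors,
        "district_office": small_config.n_districts,
        "neighbourhood_centre": small_config.n_neighbourhoods,
        "tract_centroid": small_config.n_tracts,
        "grid_centroid": small_config.n_grid_points,
        "mother_home": small_config.n_mothers,
    }


def test_full_scale_counts_are_seoul_shaped():
    # the full-scale config carries the real study's counts; building it is
    # infeasible for dense factorisation, so only validate the configuration
    assert (FULL_SCALE.n_mothers, FULL_SCALE.n_tracts) == (46007, 16230)
    assert FULL_SCALE.n_background_monitors + FULL_SCALE.n_roadside_monitors == 37
    assert (FULL_SCALE.n_districts, FULL_SCALE.n_neighbourhoods, FULL_SCALE.n_grid_points) == (25, 422, 610)


def test_every_point_in_extent_and_exactly_one_district(small_region, small_config):
    L = small_config.extent_m
    for role, pts in small_region.points.items():
        assert pts["x"].between(0, L).all() and pts["y"].between(0, L).all(), role
        assert pts["district_id"].between(0, small_config.n_districts - 1).all(), role
    # districts partition the extent: every tract centroid's containing rect
    # agrees with its recorded district
    rects = small_region.district_rects
    tr = small_region.points["tract_centroid"]
    for d, (x0, y0, x1, y1) in enumerate(rects):
        sub = tr[tr["district_id"] == d]
        assert ((sub["x"] >= x0) & (sub["x"] <= x1)).all()
        assert ((sub["y"] >= y0) & (sub["y"] <= y1)).all()


def test_neighbourhoods_nest_in_districts(small_region):
    tr = small_region.points["tract_centroid"]
    nb_parent = small_region.neighbourhood_district
    assert (tr["district_id"].to_numpy() == nb_parent[tr["neighbourhood_id"].to_numpy()]).all()
    # every neighbourhood belongs to exactly one district and all are used
    assert set(nb_parent) == set(range(small_region.n_districts))


def test_one_monitor_and_office_per_district(small_region):
    for role in ("monitor_background", "district_office"):
        districts = small_region.points[role]["district_id"]
        assert sorted(districts) == list(range(small_region.n_districts))


def test_mothers_are_tract_centroids(small_region):
    tract_u = set(small_region.points["tract_centroid"]["u_idx"])
    assert set(small_region.points["mother_home"]["u_idx"]) <= tract_u


def test_same_seed_bit_identical_different_seed_not(small_config):
    a = build_geography(small_config)
    b = build_geography(small_config)
    for role in a.points:
        pd.testing.assert_frame_equal(a.points[role], b.points[role])
    np.testing.assert_array_equal(a.covariates.values, b.covariates.values)
    c = build_geography(RegionConfig(**{**small_config.to_dict(), "seed": 99}))
    assert not np.array_equal(a.points["tract_centroid"][["x", "y"]].to_numpy(),
                              c.points["tract_centroid"][["x", "y"]].to_numpy())


def test_grid_is_regular_lattice(small_region):
    g = small_region.points["grid_centroid"]
    xs = np.unique(g["x"].round(6))
    assert len(xs) <= int(np.ceil(np.sqrt(len(g))))
    assert np.allclose(np.diff(xs), np.diff(xs)[0])


@pytest.mark.parametrize("bad", [
    dict(n_districts=0),
    dict(region_extent_km=-1),
    dict(n_background_monitors=3),        # must equal n_districts
    dict(n_neighbourhoods=2),             # fewer neighbourhoods than districts
    dict(n_tracts=5),                     # fewer tracts than neighbourhoods
])
def test_invalid_configs_raise(bad):
    base = dict(n_districts=4, n_neighbourhoods=8, n_tracts=120, n_mothers=50)
    with pytest.raises(ConfigurationError):
        RegionConfig(**{**base, **bad})


class TestMotherSampling:
    def test_single_weighted_neighbourhood_gets_all_homes(self, small_region):
        region = build_geography(small_region.config)
        region.birth_weights = np.zeros_like(region.birth_weights)
        region.birth_weights[3] = 1.0
        d = int(region.neighbourhood_district[3])
        counts = np.zeros(region.n_districts, int)
        counts[d] = 40
        homes = sample_mother_homes(region, counts, rng=np.random.default_rng(0))
        assert (homes["neighbourhood_id"] == 3).all()

    def test_zero_weight_with_demand_raises(self, small_region):
        region = build_geography(small_region.config)
        region.birth_weights = np.zeros_like(region.birth_weights)
        counts = np.zeros(region.n_districts, int)
        counts[0] = 5
        with pytest.raises(ConfigurationError):
            sample_mother_homes(region, counts, rng=np.random.default_rng(0))

    def test_exhaustive_without_replacement_selects_each_centroid_once(self, small_region):
        tr = small_region.points["tract_centroid"]
        counts = tr["district_id"].value_counts().reindex(
            range(small_region.n_districts), fill_value=0).to_numpy()
        homes = sample_mother_homes(small_region, counts,
                                    rng=np.random.default_rng(1), replace=False)
        assert sorted(homes["u_idx"].tolist()) == sorted(tr["u_idx"].tolist())

    def test_overdemand_without_replacement_raises(self, small_region):
        counts = np.full(small_region.n_districts, 10_000)
        with pytest.raises(ConfigurationError):
            sample_mother_homes(small_region, counts, rng=np.random.default_rng(1),
                                replace=False)

    def test_equal_weights_sampling_matches_multinomial_expectation(self, small_region):
        # with equal birth weights the expected number of homes per
        # neighbourhood is demand * n_tracts_nb / n_tracts_district
        region = build_geography(small_region.config)
        region.birth_weights = np.ones_like(region.birth_weights)
        demand = 4000
        counts = np.zeros(region.n_districts, int)
        counts[0] = demand
        homes = sample_mother_homes(region, counts, rng=np.random.default_rng(5))
        tr = region.points["tract_centroid"]
        nbs = tr.loc[tr["district_id"] == 0, "neighbourhood_id"]
        tracts_per_nb = nbs.value_counts()
        got = homes["neighbourhood_id"].value_counts()
        for nb, k in tracts_per_nb.items():
            p = k / len(nbs)
            expect = demand * p
            se = np.sqrt(demand * p * (1 - p))
            assert abs(got.get(nb, 0) - expect) < 4 * se


class TestCovariates:
    def test_standardised_over_tracts(self, small_region):
        X = small_region.covariates_for("tract_centroid")
        assert np.allclose(X.mean(axis=0), 0, atol=1e-6)
        assert np.allclose(X.var(axis=0), 1, atol=1e-6)

    def test_shared_coordinates_share_covariates(self, small_region):
        mothers = small_region.points["mother_home"]
        tracts = small_region.points["tract_centroid"].set_index("u_idx")
        Xm = small_region.covariates_for("mother_home")
        Xt = small_region.covariates.values
        np.testing.assert_array_equal(Xm, Xt[mothers["u_idx"].to_numpy()])

    def test_positive_spatial_autocorrelation_at_short_lags(self, small_region):
        # brute-force Moran-type statistic on a 100-point subsample: nearby
        # pairs should have positively correlated covariate values
        rng = np.random.default_rng(3)
        idx = rng.choice(len(small_region.coords), 100, replace=False)
        xy = small_region.coords[idx]
        X = small_region.covariates.values[idx]
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        near = (d > 0) & (d < 0.15 * small_region.config.extent_m)
        for j in range(X.shape[1]):
            z = X[:, j] - X[:, j].mean()
            moran = (z[:, None] * z[None])[near].mean() / z.var()
            assert moran > 0.1, f"covariate {j} lacks short-range structure"


def test_csv_and_geojson_round_trip(tmp_path, small_region):
    region_to_csv(small_region, tmp_path / "pts.csv")
    back = region_from_csv(tmp_path / "pts.csv")
    for role, pts in small_region.points.items():
        np.testing.assert_allclose(back[role][["x", "y"]].to_numpy(),
                                   pts[["x", "y"]].to_numpy())
        np.testing.assert_array_equal(back[role]["district_id"], pts["district_id"])
    region_to_geojson(small_region, tmp_path / "pts.geojson")
    import json
    gj = json.loads((tmp_path / "pts.geojson").read_text())
    assert gj["type"] == "FeatureCollection"
    assert len(gj["features"]) == sum(len(p) for p in small_region.points.values())


def test_split_and_largest_remainder_helpers():
    assert _split_counts(10, 3) == [4, 3, 3]
    assert sum(_split_counts(422, 25)) == 422
    shares = np.array([1.2, 2.5, 3.3])
    out = _largest_remainder(shares)
    assert out.sum() == 7 and (out >= np.floor(shares)).all()
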