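"""Generator contracts: determinism, invariants, and the mortality model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from emoc_access import (gen_census, gen_dem, gen_dwellings, gen_facilities,
                         gen_landcover, gen_mortality, gen_roads, gen_zones)
from emoc_access.synthetic import LOCAL_ROAD, NATIONAL_ROAD, PROVINCIAL_ROAD


class TestDem:
    def test_deterministic_and_seed_sensitive(self):
        a = gen_dem(64, roughness=0.5, seed=0)
        b = gen_dem(64, roughness=0.5, seed=0)
        c = gen_dem(64, roughness=0.5, seed=1)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_minimum_size_valid(self):
        dem = gen_dem(8, roughness=1.0, seed=7)
        assert dem.shape == (8, 8)
        assert np.all(np.isfinite(dem.data))
        assert dem.data.max() > dem.data.min()

    @pytest.mark.parametrize("size,rough", [(4, 0.5), (64, 0.0), (64, 1.5)])
    def test_invalid_args_rejected(self, size, rough):
        with pytest.raises(ValueError):
            gen_dem(size, roughness=rough, seed=0)


class TestLandcover:
    def test_all_four_classes_present(self):
        lc = gen_landcover(gen_dem(64, seed=0), seed=0)
        counts = np.bincount(lc.data.ravel(), minlength=4)
        assert lc.data.min() >= 0 and lc.data.max() <= 3
        assert np.all(counts[:4] > 0)

    def test_flat_dem_codes_in_range(self, grid_factory):
        flat = grid_factory(np.zeros((16, 16)))
        lc = gen_landcover(flat, seed=0)
        assert set(np.unique(lc.data)) <= {0, 1, 2, 3}

    def test_deterministic(self):
        dem = gen_dem(32, seed=3)
        assert np.array_equal(gen_landcover(dem, seed=5).data,
                              gen_landcover(dem, seed=5).data)


class TestRoads:
    def test_two_towns_single_national_spine(self):
        net = gen_roads(gen_dem(32, seed=0), n_towns=2, seed=0)
        assert len(net.roads) == 1
        assert net.roads[0].road_class == NATIONAL_ROAD

    def test_all_three_classes_present(self):
        net = gen_roads(gen_dem(64, seed=0), n_towns=6, seed=3)
        assert net.classes() == {LOCAL_ROAD, PROVINCIAL_ROAD, NATIONAL_ROAD}

    def test_network_is_connected(self):
        import shapely
        net = gen_roads(gen_dem(64, seed=0), n_towns=6, seed=3)
        merged = shapely.unary_union(net.multiline())
        merged = shapely.line_merge(merged)
        # every polyline touches the union of the others (one component)
        assert shapely.get_num_geometries(merged) >= 1
        from shapely.ops import unary_union
        lines = [r.line() for r in net.roads]
        comp = [0] * len(lines)
        # union-find over pairwise intersection
        parent = list(range(len(lines)))
        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                if lines[i].intersects(lines[j]):
                    parent[find(i)] = find(j)
        assert len({find(i) for i in range(len(lines))}) == 1

    def test_too_few_towns_rejected(self):
        with pytest.raises(ValueError):
            gen_roads(gen_dem(32, seed=0), n_towns=1, seed=0)


class TestZones:
    def test_single_zone(self):
        z = gen_zones((8, 8), 1, seed=0)
        assert np.all(z.data == 1)

    def test_partition_all_ids_present(self):
        z = gen_zones((32, 32), 4, seed=0)
        assert set(np.unique(z.data)) == {1, 2, 3, 4}
        assert z.data.shape == (32, 32)

    def test_k_exceeding_cells_rejected(self):
        with pytest.raises(ValueError):
            gen_zones((4, 4), 17, seed=0)


class TestFacilities:
    def test_requested_counts_and_tiers(self):
        net = gen_roads(gen_dem(64, seed=0), n_towns=5, seed=1)
        fac = gen_facilities(net, n_basic=4, n_comprehensive=1, seed=0)
        assert len(fac) == 5
        assert sorted(fac.tiers).count("basic") == 4
        assert fac.tiers.count("comprehensive") == 1

    def test_on_major_roads(self):
        net = gen_roads(gen_dem(64, seed=0), n_towns=5, seed=1)
        fac = gen_facilities(net, 4, 1, seed=0)
        d = net.distance_to(fac.points[:, 0], fac.points[:, 1], min_class=PROVINCIAL_ROAD)
        assert np.all(d < 50.0)  # within one cell of a class-5/6 polyline

    def test_deterministic_and_empty_rejected(self):
        net = gen_roads(gen_dem(32, seed=0), n_towns=3, seed=1)
        a = gen_facilities(net, 2, 1, seed=9)
        b = gen_facilities(net, 2, 1, seed=9)
        assert np.array_equal(a.points, b.points)
        with pytest.raises(ValueError):
            gen_facilities(net, 0, 0, seed=0)


class TestDwellings:
    def test_count_and_infrastructure_definition(self):
        dem = gen_dem(48, seed=0, cell=250.0)
        net = gen_roads(dem, n_towns=4, seed=1)
        zones = gen_zones(dem.shape, 4, seed=2, transform=dem.transform)
        pts, infra = gen_dwellings(net, zones, n_points=1598, seed=3)
        assert len(pts) == 1598
        rr, cc = zones.transform.world_to_cell(pts[:, 0], pts[:, 1])
        expected = np.zeros(zones.shape, dtype=bool)
        expected[rr, cc] = True
        assert np.array_equal(infra.data, expected)
        # every zone covered
        assert set(np.unique(zones.data[infra.data])) == set(np.unique(zones.data))

    def test_clustered_closer_to_roads_than_uniform(self):
        dem = gen_dem(48, seed=5, cell=250.0)
        net = gen_roads(dem, n_towns=4, seed=6)
        zones = gen_zones(dem.shape, 3, seed=7, transform=dem.transform)
        pts, _ = gen_dwellings(net, zones, n_points=800, seed=8)
        rng = np.random.default_rng(8)
        xmin, ymin, xmax, ymax = zones.transform.extent(zones.shape)
        uni = np.column_stack([rng.uniform(xmin, xmax, 800), rng.uniform(ymin, ymax, 800)])
        d_dwell = net.distance_to(pts[:, 0], pts[:, 1]).mean()
        d_uni = net.distance_to(uni[:, 0], uni[:, 1]).mean()
        assert d_dwell < d_uni

    def test_impossible_coverage_rejected(self):
        dem = gen_dem(8, seed=0)
        net = gen_roads(dem, n_towns=2, seed=0)
        zones = gen_zones(dem.shape, 60, seed=0, transform=dem.transform)
        with pytest.raises(RuntimeError, match="zones"):
            gen_dwellings(net, zones, n_points=2, seed=0, max_retries=3)


class TestMortality:
    def test_null_model_mmr_near_baseline(self):
        # beta_r = beta_s = 0: pooled MMR ~ exp(beta0) within sampling error
        beta0 = np.log(300.0)
        births = np.full(32, 10_000)
        tab, _ = gen_mortality(np.linspace(0, 1, 32), 0, births, (beta0, 0.0, 0.0),
                               years=5, seed=0)
        pooled = 100_000.0 * tab["deaths"].sum() / tab["births"].sum()
        total_deaths = tab["deaths"].sum()
        rel_err = 3.0 / np.sqrt(total_deaths)
        assert abs(pooled - 300.0) / 300.0 < max(rel_err, 0.01 + rel_err)

    def test_positive_effect_induces_positive_correlation(self):
        r = np.linspace(0, 1, 32)
        births = np.full(32, 50_000)
        tab, _ = gen_mortality(r, 0, births, (np.log(200.0), 1.0, 0.0), years=5, seed=1)
        mmr = tab.groupby("zone").apply(
            lambda g: 100_000.0 * g["deaths"].sum() / g["births"].sum(),
            include_groups=False)
        rho, _ = spearmanr(r, mmr.sort_index())
        assert rho > 0.5

    def test_deterministic_and_invariants(self):
        r = np.array([0.1, 0.9])
        a, truth = gen_mortality(r, 1, [500, 500], (5.0, 0.5, -0.2), years=3, seed=4)
        b, _ = gen_mortality(r, 1, [500, 500], (5.0, 0.5, -0.2), years=3, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert (a["deaths"] <= a["births"]).all()
        assert truth.beta_remoteness == 0.5
        with pytest.raises(ValueError):
            gen_mortality(r, 1, [-1, 500], (5.0, 0.5, -0.2), seed=0)


def test_census_fractions_and_determinism():
    zones = gen_zones((16, 16), 3, seed=0)
    a = gen_census(zones, seed=1)
    b = gen_census(zones, seed=1)
    pd.testing.assert_frame_equal(a, b)
    assert list(a["zone"]) == [1, 2, 3]
    assert (a["population"] >= 0).all()
    assert (a["female_fraction"] == 0.5).all()
    assert (a["fertile_fraction"] == 0.43).all()
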