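import numpy as np
import pytest

from schooltravel import CityConfig, ConfigurationError, ScenarioSpec, \
    build_city, build_grid, place_households, place_schools
from schooltravel.city import assign_schools, zone_of

from conftest import tiny_config


class TestBuildGrid:
    def test_default_cell_count_matches_brute_force_union(self, default_config):
        grid = build_grid(default_config)
        # oracle: enumerate every road coordinate and deduplicate via a set
        c = default_config.cells_per_segment
        p = default_config.positions_per_road
        coords = set()
        for road in range(default_config.n_roads_per_axis):
            for offset in range(p):
                coords.add((road * c, offset))   # vertical road
                coords.add((offset, road * c))   # horizontal road
        assert grid.n_cells == len(coords) == 31201
        assert coords == set(zip(grid.xs.tolist(), grid.ys.tolist()))

    def test_minimal_grid_has_eight_cells(self):
        config = CityConfig(city_size_m=40.0, n_roads_per_axis=2,
                            segments_per_road=1, cells_per_segment=2,
                            cell_size_m=20.0, n_schools=1, n_households=1)
        grid = build_grid(config)
        assert grid.n_cells == 8
        assert set(zip(grid.xs.tolist(), grid.ys.tolist())) == {
            (0, 0), (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1), (2, 2)
        }

    def test_initial_safety_from_background_only(self, default_config):
        grid = build_grid(default_config)
        expected = 1.0 - 1.5 ** -0.6
        assert expected == pytest.approx(0.216, abs=5e-4)
        assert np.allclose(grid.S, expected)
        assert np.allclose(grid.W, 1.5)

    def test_intersections_are_shared_cells(self, default_config):
        grid = build_grid(default_config)
        pairs = set(zip(grid.xs.tolist(), grid.ys.tolist()))
        assert len(pairs) == grid.n_cells  # no duplicated coordinates


class TestPlaceSchools:
    def test_baseline_zone_centres(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(n_schools=4, n_households=10)
        schools = place_schools(grid, spec, np.random.default_rng(0))
        # 2x2 zones of an 8 km city: centres at (2,2), (2,6), (6,2), (6,6) km
        # which are road intersections (cell coordinate 100 = 2000 m / 20 m)
        got = sorted(zip(schools.x.tolist(), schools.y.tolist()))
        assert got == [(100, 100), (100, 300), (300, 100), (300, 300)]

    def test_two_zone_centres(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(n_schools=2, n_households=10)
        schools = place_schools(grid, spec, np.random.default_rng(0))
        got = sorted(zip(schools.x.tolist(), schools.y.tolist()))
        assert got == [(100, 200), (300, 200)]  # (2 km, 4 km), (6 km, 4 km)

    def test_eight_schools_skip_city_centre(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(n_schools=8, n_households=10)
        schools = place_schools(grid, spec, np.random.default_rng(0))
        assert len(schools) == 8
        centre_zone = zone_of([200], [200], (3, 3), default_config)[0]
        assert centre_zone not in set(schools.zone.tolist())

    def test_random_placement_is_seeded(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(placement_rule="random_citywide", n_schools=4,
                            n_households=10)
        a = place_schools(grid, spec, np.random.default_rng(42))
        b = place_schools(grid, spec, np.random.default_rng(42))
        assert np.array_equal(a.cell, b.cell)
        assert len(set(a.cell.tolist())) == 4  # distinct cells

    def test_random_within_zone_stays_in_zone(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(placement_rule="random_within_zone", n_schools=4,
                            n_households=10)
        schools = place_schools(grid, spec, np.random.default_rng(3))
        zones = zone_of(schools.x, schools.y, spec.zone_layout, default_config)
        assert np.array_equal(zones, schools.zone)


class TestPlaceHouseholds:
    def test_distinct_cells_and_uniform_attributes(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(n_schools=4, n_households=3000)
        hh = place_households(grid, spec, np.random.default_rng(7))
        assert len(set(hh.cell.tolist())) == 3000
        assert np.all((hh.concern > 0) & (hh.concern < 1))
        assert np.all((hh.attitude > 0) & (hh.attitude < 1))
        # law of large numbers at fixed seed
        assert hh.concern.mean() == pytest.approx(0.5, abs=0.02)
        assert hh.attitude.mean() == pytest.approx(0.5, abs=0.02)

    def test_households_avoid_school_cells(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(n_schools=4, n_households=3000)
        rng = np.random.default_rng(1)
        schools = place_schools(grid, spec, rng)
        hh = place_households(grid, spec, rng, schools)
        assert not set(hh.cell.tolist()) & set(schools.cell.tolist())

    def test_capacity_error(self):
        config = tiny_config(n_households=3)
        grid = build_grid(config)
        spec = ScenarioSpec(n_schools=1, n_households=10**6, zone_layout=(1, 1))
        with pytest.raises(ConfigurationError, match="households"):
            place_households(grid, spec, np.random.default_rng(0))

    def test_seed_determinism(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(n_schools=4, n_households=100)
        a = place_households(grid, spec, np.random.default_rng(9))
        b = place_households(grid, spec, np.random.default_rng(9))
        assert np.array_equal(a.cell, b.cell)
        assert np.array_equal(a.concern, b.concern)
        assert np.array_equal(a.attitude, b.attitude)


class TestAssignSchools:
    def test_enrolment_conservation(self, baseline_city):
        assert baseline_city.schools.enrolment.sum() == len(baseline_city.households)

    def test_household_on_school_cell_gets_that_school(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(n_schools=4, n_households=1)
        schools = place_schools(grid, spec, np.random.default_rng(0))
        hh = place_households(grid, spec, np.random.default_rng(0))
        hh.cell = np.array([schools.cell[2]])
        hh.x = grid.xs[hh.cell].astype(np.int64)
        hh.y = grid.ys[hh.cell].astype(np.int64)
        assign_schools(hh, schools, spec, grid)
        assert hh.school_id[0] == 2
        assert hh.distance_miles[0] == 0.0

    def test_baseline_nearest_equals_own_zone(self, default_config):
        """With evenly placed schools the zone school is the nearest school."""
        grid = build_grid(default_config)
        spec_near = ScenarioSpec(n_schools=4, n_households=500)
        rng = np.random.default_rng(21)
        schools = place_schools(grid, spec_near, rng)
        hh = place_households(grid, spec_near, rng, schools)
        assign_schools(hh, schools, spec_near, grid)
        by_nearest = hh.school_id.copy()
        spec_zone = ScenarioSpec(n_schools=4, n_households=500,
                                 catchment_rule="own_zone")
        assign_schools(hh, schools, spec_zone, grid)
        assert np.array_equal(by_nearest, hh.school_id)

    def test_own_zone_without_school_is_an_error(self, default_config):
        grid = build_grid(default_config)
        spec = ScenarioSpec(placement_rule="random_citywide",
                            catchment_rule="own_zone", n_schools=4,
                            n_households=10, zone_layout=(2, 2))
        rng = np.random.default_rng(0)
        schools = place_schools(grid, spec, rng)
        schools.zone = np.array([0, 1, 2, 2])  # zone 3 lost its school
        hh = place_households(grid, spec, rng, schools)
        with pytest.raises(ConfigurationError, match="zone"):
            assign_schools(hh, schools, spec, grid)


class TestBuildCity:
    def test_identical_seed_identical_city(self):
        a = build_city(CityConfig(n_households=200, seed=13))
        b = build_city(CityConfig(n_households=200, seed=13))
        assert np.array_equal(a.households.cell, b.households.cell)
        assert np.array_equal(a.households.concern, b.households.concern)
        assert np.array_equal(a.schools.cell, b.schools.cell)
        assert np.array_equal(a.households.route_flat, b.households.route_flat)

    def test_baseline_distance_bound(self, baseline_city):
        # 2x2 zones of an 8 km city: no child can be farther than 8 km by road
        assert baseline_city.households.distance_miles.max() <= 8000 / 1609.34

    def test_occupancy_is_exclusive(self, baseline_city):
        cells = set(baseline_city.households.cell.tolist())
        assert len(cells) == len(baseline_city.households)
        assert not cells & set(baseline_city.schools.cell.tolist())


def test_zone_boundary_goes_to_lower_zone(default_config):
    # cell x = 200 (4000 m) lies exactly on the 2x2 boundary
    assert zone_of([200], [50], (2, 2), default_config)[0] == 0
    assert zone_of([201], [50], (2, 2), default_config)[0] == 2  # zx=1, zy=0
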