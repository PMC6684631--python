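import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seafloorbgc.geomap import (
    EARTH_RADIUS_KM,
    BasementPorosityModel,
    GeothermParams,
    Grid,
    ZoneThresholds,
    ZONES,
    basement_pore_column,
    classify_zone,
    global_grid_edges,
    habitable_basement_thickness,
    integrate_volume,
    isotherm_depth,
    mean_sedimentation_rate,
    zone_areas,
)

UNIFORM_K = GeothermParams(t_seafloor=2.0, k_sediment=1.0, k_basement=1.0)


def make_global_grid(values_fn, resolution=6.0, units="m"):
    lat_edges, lon_edges = global_grid_edges(resolution)
    shape = (lat_edges.size - 1, lon_edges.size - 1)
    return Grid(
        lat_edges=lat_edges,
        lon_edges=lon_edges,
        values=values_fn(shape),
        units=units,
    )


class TestGridGeometry:
    def test_areas_sum_to_sphere(self):
        grid = make_global_grid(np.ones)
        sphere = 4 * np.pi * EARTH_RADIUS_KM**2
        assert grid.cell_areas_km2().sum() == pytest.approx(sphere, rel=1e-10)

    def test_rejects_shape_mismatch(self):
        lat, lon = global_grid_edges(6.0)
        with pytest.raises(ValueError):
            Grid(lat_edges=lat, lon_edges=lon, values=np.ones((3, 3)))

    def test_rejects_non_monotone_edges(self):
        with pytest.raises(ValueError):
            Grid(
                lat_edges=np.array([0.0, -1.0, 2.0]),
                lon_edges=np.array([0.0, 1.0]),
                values=np.ones((2, 1)),
            )


class TestIsothermDepth:
    def test_uniform_closed_form(self):
        # depth = k * dT / q with q in W m^-2
        assert isotherm_depth(100.0, 0.0, UNIFORM_K) == pytest.approx(1200.0)

    def test_two_layer(self):
        assert isotherm_depth(100.0, 500.0) == pytest.approx(1900.0)

    def test_doubling_heatflow_halves_depth(self):
        d1 = isotherm_depth(50.0, 0.0, UNIFORM_K)
        d2 = isotherm_depth(100.0, 0.0, UNIFORM_K)
        assert d1 == pytest.approx(2 * d2)

    def test_isotherm_within_sediment(self):
        # hot enough that 122 degC is reached inside the sediment column
        d = isotherm_depth(200.0, 5000.0, UNIFORM_K)
        assert d == pytest.approx(600.0)
        assert d < 5000.0

    @given(st.floats(20.0, 400.0), st.floats(20.0, 400.0))
    def test_monotone_decreasing_in_heatflow(self, q1, q2):
        lo, hi = sorted([q1, q2])
        assert isotherm_depth(hi, 300.0) <= isotherm_depth(lo, 300.0)

    def test_monotone_in_conductivity(self):
        shallow = isotherm_depth(100.0, 0.0, GeothermParams(k_sediment=1.0, k_basement=1.0))
        deep = isotherm_depth(100.0, 0.0, GeothermParams(k_sediment=2.0, k_basement=2.0))
        assert deep > shallow

    def test_rejects_nonpositive_heatflow(self):
        with pytest.raises(ValueError):
            isotherm_depth(0.0, 100.0)

    def test_vectorized(self):
        q = np.array([50.0, 100.0, 200.0])
        d = isotherm_depth(q, np.zeros(3), UNIFORM_K)
        assert d == pytest.approx([2400.0, 1200.0, 600.0])


class TestHabitableThickness:
    def test_isotherm_above_basement(self):
        assert habitable_basement_thickness(400.0, 500.0) == 0.0

    def test_two_layer_case(self):
        assert habitable_basement_thickness(1900.0, 500.0) == pytest.approx(1400.0)

    def test_zero_sediment(self):
        assert habitable_basement_thickness(1200.0, 0.0) == pytest.approx(1200.0)


class TestPoreColumn:
    def test_full_column_75m(self):
        assert basement_pore_column(1000.0) == pytest.approx(75.0)
        assert basement_pore_column(5000.0) == pytest.approx(75.0)

    def test_zero(self):
        assert basement_pore_column(0.0) == 0.0

    def test_constant_segment(self):
        assert basement_pore_column(250.0) == pytest.approx(25.0)

    def test_midway_linear_segment(self):
        # 500 m at 10% + first 250 m of the ramp: integral phi dz = 21.875 m
        expected = 50.0 + 0.10 / 500.0 * (500.0 * 250.0 - 0.5 * 250.0**2)
        assert basement_pore_column(750.0) == pytest.approx(expected)

    @given(st.floats(0.0, 5000.0))
    def test_never_exceeds_75(self, h):
        assert basement_pore_column(h) <= 75.0 + 1e-9

    def test_custom_model_validation(self):
        with pytest.raises(ValueError):
            BasementPorosityModel(phi_upper=0.1, z_break=1000.0, z_zero=500.0)


class TestSedimentationRate:
    def test_basic(self):
        assert mean_sedimentation_rate(500.0, 100.0) == pytest.approx(5.0)

    def test_zero_thickness(self):
        assert mean_sedimentation_rate(0.0, 50.0) == 0.0

    def test_threshold_boundary(self):
        assert mean_sedimentation_rate(700.0, 20.0) == pytest.approx(35.0)

    def test_rejects_zero_age(self):
        with pytest.raises(ValueError):
            mean_sedimentation_rate(100.0, 0.0)


class TestClassifyZone:
    @pytest.mark.parametrize(
        "thickness, rate, expected",
        [
            (600.0, 10.0, "sulfate_depleted"),
            (100.0, 40.0, "sulfate_depleted"),
            (100.0, 10.0, "oxic_to_basement"),
            (300.0, 20.0, "sulfate_to_basement"),
            (150.0, 15.0, "oxic_to_basement"),  # boundary inclusive
            (500.0, 35.0, "sulfate_to_basement"),  # boundary inclusive
            (0.0, 0.0, "oxic_to_basement"),
        ],
    )
    def test_cases(self, thickness, rate, expected):
        assert classify_zone(thickness, rate) == expected

    @given(st.floats(0, 2000), st.floats(0, 100), st.floats(0, 2000), st.floats(0, 100))
    def test_monotone_toward_reduction(self, h1, r1, h2, r2):
        """More thickness or faster burial never moves toward oxidation."""
        lo = classify_zone(min(h1, h2), min(r1, r2))
        hi = classify_zone(max(h1, h2), max(r1, r2))
        assert ZONES.index(hi) >= ZONES.index(lo)

    def test_array_input_codes(self):
        codes = classify_zone(np.array([600.0, 100.0, 300.0]), np.array([10.0, 10.0, 20.0]))
        assert list(codes) == [2, 0, 1]

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ZoneThresholds(o2_thickness_max=600.0)


class TestIntegrateVolume:
    def test_constant_one_meter_global(self):
        grid = make_global_grid(np.ones)
        expected = 4 * np.pi * EARTH_RADIUS_KM**2 * 1e-3  # 5.101e5 km^3
        assert integrate_volume(grid) == pytest.approx(expected, rel=1e-10)
        assert integrate_volume(grid) == pytest.approx(5.101e5, rel=1e-3)

    def test_all_masked_zero(self):
        grid = make_global_grid(np.ones)
        mask = grid.like(np.zeros_like(grid.values))
        assert integrate_volume(grid, mask) == 0.0

    def test_hemispheric_mask_halves(self):
        grid = make_global_grid(np.ones)
        mask_values = np.zeros_like(grid.values)
        mask_values[grid.lat_centers > 0, :] = 1.0
        mask = grid.like(mask_values)
        assert integrate_volume(grid, mask) == pytest.approx(
            integrate_volume(grid) / 2, rel=1e-10
        )

    def test_mask_mismatch_rejected(self):
        grid = make_global_grid(np.ones, resolution=6.0)
        other = make_global_grid(np.ones, resolution=10.0)
        with pytest.raises(ValueError):
            integrate_volume(grid, other)


class TestZoneAreas:
    def test_single_category(self):
        thickness = make_global_grid(lambda s: np.full(s, 1000.0))
        age = make_global_grid(lambda s: np.full(s, 100.0), units="Ma")
        out = zone_areas(thickness, age)
        assert out["sulfate_depleted"]["fraction"] == pytest.approx(1.0)
        assert out["oxic_to_basement"]["area_km2"] == 0.0

    def test_fractions_partition(self, coarse_grids):
        _, thickness, age = coarse_grids
        out = zone_areas(thickness, age)
        total = sum(v["fraction"] for v in out.values())
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_extreme_thresholds_rule_order(self):
        thickness = make_global_grid(lambda s: np.full(s, 1e5))
        age = make_global_grid(lambda s: np.full(s, 1.0), units="Ma")
        wide = ZoneThresholds(
            o2_thickness_max=np.inf,
            o2_rate_max=np.inf,
            so4_thickness_max=np.inf,
            so4_rate_max=np.inf,
        )
        out = zone_areas(thickness, age, thresholds=wide)
        assert out["oxic_to_basement"]["fraction"] == pytest.approx(1.0)

    def test_ocean_mask_restricts(self, coarse_grids):
        _, thickness, age = coarse_grids
        mask = thickness.like(np.zeros_like(thickness.values))
        mask.values[:5, :] = 1.0
        out = zone_areas(thickness, age, ocean_mask=mask)
        total_area = sum(v["area_km2"] for v in out.values())
        expected = (thickness.cell_areas_km2() * mask.values).sum()
        assert total_area == pytest.approx(expected, rel=1e-12)

    def test_zero_thickness_all_oxic(self):
        thickness = make_global_grid(np.zeros)
        age = make_global_grid(lambda s: np.full(s, 50.0), units="Ma")
        out = zone_areas(thickness, age)
        assert out["oxic_to_basement"]["fraction"] == pytest.approx(1.0)
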