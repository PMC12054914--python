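"""Scalar factor formulas against hand-evaluated oracles, plus properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sandfix import (
    GridSpec,
    air_density,
    convert_wind_height,
    crust_factor,
    erodibility_factor,
    fractional_cover,
    idw_interpolate,
    ridge_roughness,
    roughness_factor,
    snow_factor,
    soil_wetness_factor,
    vegetation_factor,
    weather_factor,
    wind_intensity_factor,
)
from sandfix.weather import MonthlyClimateSummary


class TestWindHeightConversion:
    @pytest.mark.parametrize(
        "u, z, expected",
        [
            (10.0, 10.0, 7.4795),   # 10*4.87/ln(672.58)
            (0.0, 10.0, 0.0),
            (6.0, 2.0, 6.0012),     # near-identity at 2 m
        ],
    )
    def test_known_values(self, u, z, expected):
        assert convert_wind_height(u, z) == pytest.approx(expected, rel=1e-3)

    def test_invalid_height_raises(self):
        with pytest.raises(ValueError):
            convert_wind_height(5.0, 0.05)


class TestAirDensity:
    @pytest.mark.parametrize(
        "el, t, expected",
        [
            (0.0, 288.15, 1.2234),
            (1.2, 280.0, 1.0912),
            (0.0, 348.0 * 1.013, 1.0),
        ],
    )
    def test_known_values(self, el, t, expected):
        assert air_density(el, t) == pytest.approx(expected, rel=1e-3)

    def test_nonpositive_temperature_raises(self):
        with pytest.raises(ValueError):
            air_density(0.0, 0.0)


class TestWindIntensity:
    @pytest.mark.parametrize(
        "u2, u1, nd, expected",
        [(7.0, 5.0, 10, 280.0), (5.0, 5.0, 30, 0.0), (4.0, 5.0, 30, 0.0)],
    )
    def test_threshold_and_value(self, u2, u1, nd, expected):
        assert wind_intensity_factor(u2, u1, nd) == pytest.approx(expected)

    def test_negative_day_count_rejected(self):
        with pytest.raises(ValueError):
            wind_intensity_factor(7.0, 5.0, -1)

    @given(st.floats(5.01, 20), st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None)
    def test_nondecreasing_in_wind_above_threshold(self, u2, du):
        assert wind_intensity_factor(u2 + du, 5.0, 10) >= wind_intensity_factor(u2, 5.0, 10)


class TestSoilWetness:
    @pytest.mark.parametrize(
        "etp, r, rd, expected",
        [(100.0, 0.0, 0, 1.0), (100.0, 30.0, 5, 0.95), (10.0, 200.0, 20, 0.0)],
    )
    def test_known_values(self, etp, r, rd, expected):
        assert soil_wetness_factor(etp, r, 0.0, rd, 30) == pytest.approx(expected)

    def test_nonpositive_etp_rejected(self):
        with pytest.raises(ValueError):
            soil_wetness_factor(0.0, 10.0, 0.0, 1, 30)


class TestSnowFactor:
    def test_bare_full_and_partial_cover(self):
        assert snow_factor(np.zeros(30)) == 1.0
        assert snow_factor(np.full(30, 30.0)) == 0.0
        depths = np.zeros(30)
        depths[:3] = 30.0
        assert snow_factor(depths) == pytest.approx(0.9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            snow_factor([])


def _summary(**kw):
    base = dict(month=4, u2_mean=7.0, nd=10.0, r_mm=0.0, rd=0.0, etp_mm=100.0,
                p_snow=0.0, rho=1.2234, days_in_month=30.0)
    base.update(kw)
    return MonthlyClimateSummary(**base)


class TestWeatherFactor:
    def test_single_month_hand_value(self):
        # Wf=280, rho/g=0.124837, SW=(100-0)/100 with r=30,rd=5 -> 0.95
        m = _summary(r_mm=30.0, rd=5.0)
        assert weather_factor([m]) == pytest.approx(280 * (1.2234 / 9.8) * 0.95, rel=1e-6)
        assert weather_factor([m]) == pytest.approx(33.21, abs=5e-3)

    def test_calm_month_contributes_zero(self):
        assert weather_factor([_summary(u2_mean=3.0, nd=0.0)]) == 0.0

    def test_additive_over_months(self):
        m = _summary(r_mm=30.0, rd=5.0)
        assert weather_factor([m, m]) == pytest.approx(2 * weather_factor([m]), rel=1e-12)


class TestIDW:
    grid = GridSpec(nrows=5, ncols=5, cellsize=100.0)

    def test_single_station_gives_uniform_field(self):
        out = idw_interpolate([(250.0, 250.0, 4.2)], self.grid)
        np.testing.assert_allclose(out, 4.2)

    def test_equidistant_cell_averages_equal_weights(self):
        # stations symmetric about the center cell (250, 250)
        out = idw_interpolate([(150.0, 250.0, 2.0), (350.0, 250.0, 4.0)], self.grid)
        assert out[2, 2] == pytest.approx(3.0)

    def test_exact_at_station_cells(self):
        # station at the center of cell (row 2, col 1)
        out = idw_interpolate([(150.0, 250.0, 7.5), (400.0, 400.0, 1.0)], self.grid)
        assert out[2, 1] == 7.5

    def test_bounded_by_station_values(self, rng):
        pts = [(float(rng.uniform(0, 500)), float(rng.uniform(0, 500)), float(v))
               for v in rng.normal(size=6)]
        out = idw_interpolate(pts, self.grid)
        vals = [p[2] for p in pts]
        assert out.min() >= min(vals) - 1e-12 and out.max() <= max(vals) + 1e-12

    def test_no_stations_rejected(self):
        with pytest.raises(ValueError):
            idw_interpolate([], self.grid)


class TestErodibility:
    @pytest.mark.parametrize(
        "sa, si, cl, om, caco3, expected",
        [
            (90, 5, 5, 0.3, 1, 0.6286),
            (0, 0, 100, 0, 0, 0.299),
            (50, 25, 25, 10, 10, 0.1491),  # (29.9+15.5+4.25+0.66-25.9-9.5)/100
        ],
    )
    def test_known_values(self, sa, si, cl, om, caco3, expected):
        assert erodibility_factor(sa, si, cl, om, caco3) == pytest.approx(expected, rel=1e-3)

    def test_zero_clay_is_singular(self):
        with pytest.raises(ZeroDivisionError):
            erodibility_factor(90, 10, 0, 0.3, 1)
        arr = erodibility_factor(np.array([90.0]), np.array([10.0]), np.array([0.0]),
                                 np.array([0.3]), np.array([1.0]))
        assert np.isnan(arr).all()

    def test_canonical_constant_switch(self):
        printed = erodibility_factor(90, 5, 5, 0.3, 1)
        canonical = erodibility_factor(90, 5, 5, 0.3, 1, constant=29.09)
        assert printed - canonical == pytest.approx(0.0081, rel=1e-6)


class TestCrustFactor:
    @pytest.mark.parametrize(
        "cl, om, expected", [(0, 0, 1.0), (5, 0.3, 0.8570), (100, 0, 0.014925)]
    )
    def test_known_values(self, cl, om, expected):
        assert crust_factor(cl, om) == pytest.approx(expected, rel=1e-3)

    @given(st.floats(0, 99), st.floats(0.01, 5), st.floats(0, 20))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_clay_and_om(self, cl, dcl, om):
        assert crust_factor(cl + dcl, om) < crust_factor(cl, om)
        assert crust_factor(cl, om + 0.1) < crust_factor(cl, om)


class TestFractionalCover:
    def test_endpoints_midpoint_and_clip(self):
        assert fractional_cover(0.1, 0.1, 0.7) == 0.0
        assert fractional_cover(0.4, 0.1, 0.7) == pytest.approx(0.5)
        assert fractional_cover(0.9, 0.1, 0.7) == 1.0

    def test_percentile_defaults(self, rng):
        ndvi = rng.uniform(0.0, 0.6, size=(50, 50))
        sc = fractional_cover(ndvi)
        lo, hi = np.percentile(ndvi, [5, 95])
        mid_val = fractional_cover((lo + hi) / 2, lo, hi)
        assert mid_val == pytest.approx(0.5)
        assert sc.min() == 0.0 and sc.max() == 1.0

    def test_inverted_endpoints_rejected(self):
        with pytest.raises(ValueError):
            fractional_cover(0.5, 0.7, 0.1)


class TestVegetationFactor:
    @pytest.mark.parametrize(
        "sc, expected", [(0.0, 1.0), (0.5, 0.1119), (1.0, 0.012527)]
    )
    def test_percent_scale_values(self, sc, expected):
        assert vegetation_factor(sc) == pytest.approx(expected, rel=1e-3)

    def test_fraction_scale_literal_reading(self):
        assert vegetation_factor(1.0, cover_scale="fraction") == pytest.approx(
            math.exp(-0.0438), rel=1e-12
        )

    @given(st.floats(0, 0.99), st.floats(0.001, 0.01))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_cover(self, sc, d):
        assert vegetation_factor(min(sc + d, 1.0)) < vegetation_factor(sc)

    def test_out_of_range_cover_rejected(self):
        with pytest.raises(ValueError):
            vegetation_factor(1.2)


class TestRoughness:
    @pytest.mark.parametrize(
        "kr, expected",
        [(0.0, 1.0), (1.0, 0.5769), (0.5, math.exp(0.93 - 2.41 * 0.5**0.94))],
    )
    def test_known_values(self, kr, expected):
        assert roughness_factor(kr) == pytest.approx(expected, rel=1e-3)

    def test_negative_roughness_rejected(self):
        with pytest.raises(ValueError):
            roughness_factor(-0.1)

    def test_flat_dem_gives_zero_kr_everywhere(self):
        grid = GridSpec(nrows=6, ncols=6, cellsize=500.0)
        kr = ridge_roughness(np.full(grid.shape, 1234.5), grid, length_m=1000.0)
        np.testing.assert_allclose(kr, 0.0)

    def test_kr_unit_convention_and_quadratic_law(self):
        # alternating-column DEM: every window spans the full 5 m relief
        grid = GridSpec(nrows=4, ncols=6, cellsize=1000.0)
        dem = np.tile([1000.0, 1005.0], (4, 3))
        kr = ridge_roughness(dem, grid, length_m=1000.0)
        np.testing.assert_allclose(kr, 0.5)  # 0.2*25/1000 m = 0.5 cm
        dem2 = np.tile([1000.0, 1010.0], (4, 3))
        np.testing.assert_allclose(ridge_roughness(dem2, grid, 1000.0), 4 * kr)

    def test_window_smaller_than_cell_rejected(self):
        grid = GridSpec(nrows=4, ncols=4, cellsize=1000.0)
        with pytest.raises(ValueError):
            ridge_roughness(np.zeros(grid.shape), grid, length_m=100.0)


def test_vectorised_factors_match_per_cell_loop(rng):
    """Raster evaluation equals the scalar formula applied cell by cell."""
    sa = rng.uniform(40, 80, size=(6, 6))
    si = rng.uniform(5, 15, size=(6, 6))
    cl = 100 - sa - si  # >= 5 by construction
    om = rng.uniform(0.1, 3, size=(6, 6))
    ca = rng.uniform(0, 5, size=(6, 6))
    ef = erodibility_factor(sa, si, cl, om, ca)
    scf = crust_factor(cl, om)
    sc = rng.uniform(0, 1, size=(6, 6))
    c = vegetation_factor(sc)
    for i in range(6):
        for j in range(6):
            assert ef[i, j] == pytest.approx(
                erodibility_factor(sa[i, j], si[i, j], cl[i, j], om[i, j], ca[i, j]), rel=1e-12)
            assert scf[i, j] == pytest.approx(crust_factor(cl[i, j], om[i, j]), rel=1e-12)
            assert c[i, j] == pytest.approx(vegetation_factor(sc[i, j]), rel=1e-12)


def test_factor_ranges_on_synthetic_scene(stack):
    """SCF, C in (0,1]; EF in (0,1); WF >= 0 over a full synthetic scene."""
    assert (stack.SCF > 0).all() and (stack.SCF <= 1).all()
    assert (stack.C > 0).all() and (stack.C <= 1).all()
    assert (stack.EF > 0).all() and (stack.EF < 1).all()
    assert (stack.WF >= 0).all()
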