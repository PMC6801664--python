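import math

import pytest

from oracles import usno_position, usno_sun
from uvdose.solar_geometry import (
    Instant,
    Site,
    SurfaceOrientation,
    declination,
    eccentricity_factor,
    hour_angle,
    incidence_cosine,
    solar_azimuth,
    solar_position,
    zenith_elevation,
)

PISA = Site(43.72, 10.39, 4.0)


class TestDeclination:
    def test_summer_solstice_matches_printed_value(self):
        assert declination(172) == pytest.approx(23.45, abs=0.05)

    def test_near_zero_at_spring_equinox(self):
        assert abs(declination(80)) < 0.5

    def test_december_solstice(self):
        assert declination(355) == pytest.approx(-23.4, abs=0.1)

    @pytest.mark.parametrize("n", [0, 367])
    def test_rejects_out_of_range_day(self, n):
        with pytest.raises(ValueError):
            declination(n)


class TestEccentricity:
    def test_annual_extremes(self):
        values = [eccentricity_factor(n) for n in range(1, 366)]
        assert 0.96 < min(values) and max(values) < 1.04
        # perihelion within days of New Year, aphelion at mid-year
        assert min(values.index(max(values)), 364 - values.index(max(values))) < 10
        assert 178 < values.index(min(values)) < 188

    def test_summer_solstice_value(self):
        assert eccentricity_factor(172) == pytest.approx(0.9675, abs=5e-4)

    def test_january_first(self):
        assert eccentricity_factor(1) == pytest.approx(1.033, abs=1e-3)

    def test_tracks_inverse_square_distance(self):
        # c_d should follow (mean/actual distance)^2 from an ephemeris
        for n in range(5, 365, 30):
            dist = usno_sun(n, 12.0)[2]
            assert eccentricity_factor(n) == pytest.approx(dist**-2, abs=5e-3)


class TestHourAngle:
    def test_solar_noon_is_zero(self):
        assert hour_angle(Instant(172, 12.0)) == 0.0

    def test_fifteen_degrees_per_hour(self):
        assert hour_angle(Instant(172, 10.0)) == pytest.approx(-30.0)
        assert hour_angle(Instant(172, 15.5)) == pytest.approx(52.5)

    def test_clock_conversion_matches_independent_equation_of_time(self):
        rome = Site(41.89, 12.49, 21.0)
        inst = Instant(52, 12.0, convention="clock", utc_offset=1.0)
        omega = hour_angle(inst, rome)
        _, eot_min, _ = usno_sun(52, 11.0)
        expected = 15.0 * ((12.0 - 1.0 + 12.49 / 15.0 + eot_min / 60.0) - 12.0)
        assert omega == pytest.approx(expected, abs=0.05)

    def test_clock_conversion_requires_site(self):
        with pytest.raises(ValueError):
            hour_angle(Instant(52, 12.0, convention="clock", utc_offset=1.0))


class TestZenithElevation:
    def test_printed_noon_zenith(self):
        theta, alpha = zenith_elevation(43.72, 23.45, 0.0)
        assert theta == pytest.approx(20.27, abs=0.05)
        assert alpha == pytest.approx(90.0 - theta)

    def test_sun_at_zenith_when_latitude_equals_declination(self):
        theta, _ = zenith_elevation(23.45, 23.45, 0.0)
        assert theta == pytest.approx(0.0, abs=1e-5)

    def test_campaign_zenith_reproduces_printed_range(self):
        # the campaign tables' printed zenith angles follow from the
        # fixtures' clock-time convention (see docs/methods.md)
        rome = Site(41.89, 12.49, 21.0)
        geom = solar_position(rome, Instant(52, 11.5, convention="clock", utc_offset=2.0))
        assert geom.zenith == pytest.approx(58.62, abs=0.35)
        pisa_geom = solar_position(PISA, Instant(136, 11.5, convention="clock", utc_offset=2.0))
        assert pisa_geom.zenith == pytest.approx(32.95, abs=0.35)


class TestSolarAzimuth:
    def test_zero_at_noon_in_northern_midlatitudes(self):
        assert solar_azimuth(43.72, 23.45, 0.0, 20.27) == pytest.approx(0.0, abs=1e-9)

    def test_negative_east_of_south(self):
        theta, _ = zenith_elevation(43.72, 23.45, -30.0)
        assert solar_azimuth(43.72, 23.45, -30.0, theta) < 0

    def test_zenith_sun_returns_zero_by_convention(self):
        assert solar_azimuth(23.45, 23.45, 0.0, 0.0) == 0.0


class TestAgainstIndependentEphemeris:
    def test_position_within_point_three_degrees_over_a_year(self):
        worst = 0.0
        for n in range(3, 365, 11):
            for hour in (8.0, 10.5, 12.0, 13.25, 16.0):
                geom = solar_position(
                    PISA, Instant(n, hour, convention="clock", utc_offset=1.0)
                )
                zen_o, az_o, decl_o = usno_position(
                    PISA.latitude, PISA.longitude, n, hour, 1.0
                )
                if zen_o < 85.0:
                    worst = max(
                        worst,
                        abs(geom.zenith - zen_o),
                        abs(geom.azimuth - az_o),
                        abs(geom.declination - decl_o),
                    )
        assert worst < 0.3


class TestIncidenceCosine:
    def test_printed_vertical_south_value(self, case_geometry):
        ci = incidence_cosine(case_geometry, SurfaceOrientation(90.0, 0.0))
        assert ci == pytest.approx(0.346, abs=0.001)

    def test_horizontal_equals_cos_zenith(self, case_geometry):
        ci = incidence_cosine(case_geometry, SurfaceOrientation(0.0, 123.0))
        assert ci == pytest.approx(math.cos(math.radians(case_geometry.zenith)), abs=1e-12)

    def test_opposite_azimuths_negate_for_vertical_at_noon(self, case_geometry):
        s = incidence_cosine(case_geometry, SurfaceOrientation(90.0, 0.0))
        n = incidence_cosine(case_geometry, SurfaceOrientation(90.0, 180.0))
        assert s == pytest.approx(-n, abs=1e-12)

    def test_east_west_symmetry_at_noon(self, case_geometry):
        e = incidence_cosine(case_geometry, SurfaceOrientation(50.0, -90.0))
        w = incidence_cosine(case_geometry, SurfaceOrientation(50.0, 90.0))
        assert e == pytest.approx(w, abs=1e-12)


class TestValidation:
    def test_site_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            Site(91.0, 0.0)
        with pytest.raises(ValueError):
            Site(0.0, 181.0)

    def test_instant_rejects_bad_hour(self):
        with pytest.raises(ValueError):
            Instant(100, 24.0)

    def test_surface_rejects_bad_tilt(self):
        with pytest.raises(ValueError):
            SurfaceOrientation(-1.0, 0.0)
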