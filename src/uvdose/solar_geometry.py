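"""Solar geometry: sun position, time conversions and surface incidence.

Angle conventions
-----------------
All interface angles are in degrees. Surface and solar azimuths are measured
from due south, negative towards east, positive towards west, 180 = north.
The hour angle is zero at solar noon, negative before noon, 15 degrees per
hour. Day-of-year is 1-based.

The sun's declination and the equation of time are evaluated with a
Meeus-grade low-precision ephemeris (the algorithm behind the NOAA solar
calculator), accurate to a few hundredths of a degree - simple single-term
sine formulas err by up to ~1 degree near the equinoxes, which is more than
the tolerance this package promises for solar position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Site",
    "Instant",
    "SurfaceOrientation",
    "SolarGeometry",
    "declination",
    "equation_of_time",
    "eccentricity_factor",
    "solar_time",
    "hour_angle",
    "zenith_elevation",
    "solar_azimuth",
    "incidence_cosine",
    "solar_position",
]

_DEG = math.pi / 180.0

#: Reference year used to anchor day-of-year on the Julian calendar.
#: Year-to-year declination differences (< 0.25 deg) are far below every
#: tolerance used downstream.
REFERENCE_YEAR_JD0 = 2458484.5  # 2019-01-01 00:00 UT


@dataclass(frozen=True)
class Site:
    """Geographic location. Latitude positive north, longitude positive east,
    altitude in metres above sea level."""

    latitude: float
    longitude: float
    altitude: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.altitude < -430.0:
            raise ValueError(f"altitude below lowest land surface: {self.altitude}")


@dataclass(frozen=True)
class Instant:
    """A moment of a given day, either in solar time or in clock time.

    ``hour`` is decimal hours in [0, 24). For ``convention='clock'`` the
    clock->solar conversion uses the site longitude, the UTC offset and the
    equation of time.
    """

    day_of_year: int
    hour: float
    convention: str = "solar"
    utc_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.day_of_year <= 366:
            raise ValueError(f"day_of_year out of range: {self.day_of_year}")
        if not 0.0 <= self.hour < 24.0:
            raise ValueError(f"hour out of range: {self.hour}")
        if self.convention not in ("solar", "clock"):
            raise ValueError(f"unknown time convention: {self.convention!r}")


@dataclass(frozen=True)
class SurfaceOrientation:
    """Oriented plane: ``tilt`` (beta) from horizontal, ``azimuth`` (gamma)
    of the surface normal's horizontal projection (0 = south)."""

    tilt: float
    azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt <= 180.0:
            raise ValueError(f"tilt out of range: {self.tilt}")
        if not -180.0 < self.azimuth <= 180.0:
            raise ValueError(f"azimuth out of range: {self.azimuth}")


@dataclass(frozen=True)
class SolarGeometry:
    """Solar angles for one site and instant (all degrees), plus the
    Earth-Sun eccentricity correction factor."""

    declination: float
    hour_angle: float
    zenith: float
    elevation: float
    azimuth: float
    eccentricity: float

    @property
    def sun_up(self) -> bool:
        return self.elevation > 0.0


# ---------------------------------------------------------------------------
# ephemeris
# ---------------------------------------------------------------------------

def _ephemeris(julian_day: float) -> tuple[float, float]:
    """Return (declination [deg], equation of time [min]) for a Julian day.

    Low-precision Meeus solar coordinates with apparent-longitude nutation
    correction; declination accurate to ~0.01 deg, equation of time to a few
    seconds over the reference epoch.
    """
    T = (julian_day - 2451545.0) / 36525.0
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = M * _DEG
    C = (
        math.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + math.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + math.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = (125.04 - 1934.136 * T) * _DEG
    app_long = (true_long - 0.00569 - 0.00478 * math.sin(omega)) * _DEG
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = (eps0 + 0.00256 * math.cos(omega)) * _DEG
    decl = math.asin(math.sin(eps) * math.sin(app_long)) / _DEG

    y = math.tan(eps / 2.0) ** 2
    L0r = L0 * _DEG
    eot_rad = (
        y * math.sin(2 * L0r)
        - 2.0 * e * math.sin(Mr)
        + 4.0 * e * y * math.sin(Mr) * math.cos(2 * L0r)
        - 0.5 * y * y * math.sin(4 * L0r)
        - 1.25 * e * e * math.sin(2 * Mr)
    )
    return decl, 4.0 * eot_rad / _DEG


def _julian_day(day_of_year: int, hour_utc: float) -> float:
    return REFERENCE_YEAR_JD0 + (day_of_year - 1) + hour_utc / 24.0


def declination(day_of_year: int, hour_utc: float = 12.0) -> float:
    """Solar declination (degrees) for a day of the year."""
    if not 1 <= day_of_year <= 366:
        raise ValueError(f"day_of_year out of range: {day_of_year}")
    return _ephemeris(_julian_day(day_of_year, hour_utc))[0]


def equation_of_time(day_of_year: int, hour_utc: float = 12.0) -> float:
    """Equation of time (minutes; positive when the sundial leads the clock)."""
    if not 1 <= day_of_year <= 366:
        raise ValueError(f"day_of_year out of range: {day_of_year}")
    return _ephemeris(_julian_day(day_of_year, hour_utc))[1]


def eccentricity_factor(day_of_year: int) -> float:
    """Earth-Sun distance (eccentricity) correction factor c_d.

    c_d = 1 + 0.033 cos(2 pi n / 365): the squared ratio of mean to actual
    distance, maximal in early January (~1.033), minimal in early July.
    """
    if not 1 <= day_of_year <= 366:
        raise ValueError(f"day_of_year out of range: {day_of_year}")
    return 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)


# ---------------------------------------------------------------------------
# time and angles
# ---------------------------------------------------------------------------

def solar_time(clock_hour: float, day_of_year: int, longitude: float, utc_offset: float) -> float:
    """Convert clock time (decimal hours) to apparent solar time.

    solar = clock - utc_offset + longitude/15 + EoT/60.
    """
    hour_utc = clock_hour - utc_offset
    eot_min = equation_of_time(day_of_year, hour_utc % 24.0)
    return clock_hour - utc_offset + longitude / 15.0 + eot_min / 60.0


def hour_angle(instant: Instant, site: Site | None = None) -> float:
    """Hour angle omega (degrees): zero at solar noon, 15 deg/hour,
    negative before noon."""
    if instant.convention == "solar":
        t_sol = instant.hour
    else:
        if site is None:
            raise ValueError("clock-time instants need a Site for the conversion")
        t_sol = solar_time(instant.hour, instant.day_of_year, site.longitude, instant.utc_offset)
    return 15.0 * (t_sol - 12.0)


def zenith_elevation(latitude: float, decl: float, omega: float) -> tuple[float, float]:
    """Solar zenith angle theta and elevation alpha = 90 - theta (degrees)."""
    cz = (
        math.sin(latitude * _DEG) * math.sin(decl * _DEG)
        + math.cos(latitude * _DEG) * math.cos(decl * _DEG) * math.cos(omega * _DEG)
    )
    theta = math.acos(max(-1.0, min(1.0, cz))) / _DEG
    return theta, 90.0 - theta


def solar_azimuth(latitude: float, decl: float, omega: float, zenith: float) -> float:
    """Solar azimuth gamma_s (degrees, 0 = south, east negative).

    Undefined when the sun is at the zenith; returns 0 by convention there.
    """
    st = math.sin(zenith * _DEG)
    if st < 1e-9:
        return 0.0
    sin_az = math.cos(decl * _DEG) * math.sin(omega * _DEG) / st
    cos_az = (
        math.cos(zenith * _DEG) * math.sin(latitude * _DEG) - math.sin(decl * _DEG)
    ) / (st * math.cos(latitude * _DEG))
    return math.atan2(sin_az, cos_az) / _DEG


def incidence_cosine(geom: SolarGeometry, surface: SurfaceOrientation) -> float:
    """Cosine of the angle between the sun direction and the surface normal.

    May be negative (sun behind the surface). For a horizontal surface it
    equals cos(zenith).
    """
    beta = surface.tilt * _DEG
    theta = geom.zenith * _DEG
    cosinc = math.cos(beta) * math.cos(theta) + math.sin(beta) * math.sin(theta) * math.cos(
        (geom.azimuth - surface.azimuth) * _DEG
    )
    return max(-1.0, min(1.0, cosinc))


def solar_position(site: Site, instant: Instant) -> SolarGeometry:
    """All solar angles for one site and instant."""
    if instant.convention == "clock":
        hour_utc = (instant.hour - instant.utc_offset) % 24.0
    else:
        hour_utc = instant.hour
    decl = declination(instant.day_of_year, hour_utc)
    omega = hour_angle(instant, site)
    zen, elev = zenith_elevation(site.latitude, decl, omega)
    az = solar_azimuth(site.latitude, decl, omega, zen)
    return SolarGeometry(
        declination=decl,
        hour_angle=omega,
        zenith=zen,
        elevation=elev,
        azimuth=az,
        eccentricity=eccentricity_factor(instant.day_of_year),
    )
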