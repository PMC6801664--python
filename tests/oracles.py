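"""Independent oracles for cross-checking the implementation.

Deliberately written against different published sources than the package:
solar position follows the Astronomical Almanac's approximate solar
coordinates (USNO), and the tilted-sky evaluation is an independently
structured transcription of the all-weather anisotropic model. Nothing
here imports from uvdose.
"""

import math

_DEG = math.pi / 180.0
_JD0_2019 = 2458484.5


def usno_sun(day_of_year: float, hour_utc: float):
    """Approximate solar coordinates (Astronomical Almanac).

    Returns (declination deg, equation of time min, distance AU) for the
    2019 reference year used by the package.
    """
    D = _JD0_2019 + (day_of_year - 1) + hour_utc / 24.0 - 2451545.0
    g = (357.529 + 0.98560028 * D) * _DEG
    q = 280.459 + 0.98564736 * D
    L = (q + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g)) * _DEG
    dist = 1.00014 - 0.01671 * math.cos(g) - 0.00014 * math.cos(2 * g)
    e = (23.439 - 0.00000036 * D) * _DEG
    ra = math.atan2(math.cos(e) * math.sin(L), math.cos(L)) / _DEG
    decl = math.asin(math.sin(e) * math.sin(L)) / _DEG
    eot_deg = (q % 360.0) - (ra % 360.0)
    if eot_deg > 180.0:
        eot_deg -= 360.0
    if eot_deg < -180.0:
        eot_deg += 360.0
    return decl, 4.0 * eot_deg, dist


def usno_position(lat, lon, day_of_year, clock_hour, utc_offset):
    """(zenith, azimuth-from-south) via the USNO coordinates."""
    decl, eot_min, _ = usno_sun(day_of_year, clock_hour - utc_offset)
    t_sol = clock_hour - utc_offset + lon / 15.0 + eot_min / 60.0
    om = (15.0 * (t_sol - 12.0)) * _DEG
    la, de = lat * _DEG, decl * _DEG
    cz = math.sin(la) * math.sin(de) + math.cos(la) * math.cos(de) * math.cos(om)
    zen = math.acos(max(-1.0, min(1.0, cz)))
    sz = math.sin(zen)
    if sz < 1e-9:
        az = 0.0
    else:
        az = math.atan2(
            math.cos(de) * math.sin(om) / sz,
            (cz * math.sin(la) - math.sin(de)) / (sz * math.cos(la)),
        )
    return zen / _DEG, az / _DEG, decl


def perez_tilted_diffuse(dh, dni, zenith, sun_az, tilt, surf_az, extra_normal):
    """All-weather anisotropic sky diffuse on a tilted plane.

    Explicit if-chain transcription of the published model (1990 coefficient
    table), structured independently of the package's implementation.
    """
    z = zenith * _DEG
    kap = 1.041
    eps = ((dh + dni) / dh + kap * z**3) / (1 + kap * z**3)
    if eps < 1.065:
        f = (-0.008, 0.588, -0.062, -0.060, 0.072, -0.022)
    elif eps < 1.230:
        f = (0.130, 0.683, -0.151, -0.019, 0.066, -0.029)
    elif eps < 1.500:
        f = (0.330, 0.487, -0.221, 0.055, -0.064, -0.026)
    elif eps < 1.950:
        f = (0.568, 0.187, -0.295, 0.109, -0.152, -0.014)
    elif eps < 2.800:
        f = (0.873, -0.392, -0.362, 0.226, -0.462, 0.001)
    elif eps < 4.500:
        f = (1.132, -1.237, -0.412, 0.288, -0.823, 0.056)
    elif eps < 6.200:
        f = (1.060, -1.600, -0.359, 0.264, -1.127, 0.131)
    else:
        f = (0.678, -0.327, -0.250, 0.156, -1.377, 0.251)
    am = 1.0 / (math.cos(z) + 0.50572 * (96.07995 - zenith) ** -1.6364)
    delta = am * dh / extra_normal
    F1 = max(0.0, f[0] + f[1] * delta + f[2] * z)
    F2 = f[3] + f[4] * delta + f[5] * z
    b = tilt * _DEG
    cosinc = (
        math.cos(b) * math.cos(z)
        + math.sin(b) * math.sin(z) * math.cos((sun_az - surf_az) * _DEG)
    )
    a_term = max(0.0, cosinc)
    b_term = max(math.cos(85 * _DEG), math.cos(z))
    return max(
        0.0,
        dh * ((1 - F1) * (1 + math.cos(b)) / 2 + F1 * a_term / b_term + F2 * math.sin(b)),
    )
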