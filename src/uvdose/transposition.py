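"""Transposition of horizontal erythemal components to a tilted surface.

The irradiance on an oriented plane is the sum of three terms:

    I_A = I_bA + I_dA,s + I_dA,g

* beam:            I_bA   = I_er,bh * cos(incidence) / sin(elevation)
* ground-reflected I_dA,g = I_er,h * rho_UV * (1 - cos beta) / 2
* sky-diffuse      I_dA,s from the Perez all-weather anisotropic model:

    I_dA,s = I_er,dh * [ (1 - F1)(1 + cos beta)/2 + F1 a/b + F2 sin beta ]

with circumsolar brightening F1, horizon brightening F2, a = max(0, cos
incidence) and b = max(cos 85deg, cos zenith). F1 and F2 are read from the
published all-weather coefficient table, binned by sky clearness epsilon and
scaled by sky brightness Delta.

Two parameterization modes select the band in which epsilon and Delta are
evaluated:

* ``"erythemal"`` (default): from the erythemal components themselves and
  the erythemal solar constant. Self-contained - needs no extra input.
* ``"broadband"``: from the total (broadband) horizontal irradiance E_h,
  split into diffuse and direct with the Reindl correlations. This sees the
  sky the way the model's coefficients were fitted (a clear sky is "clear"
  even though the erythemal band is diffuse-dominated), at the price of one
  extra measured input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .decomposition import ERYTHEMAL_SOLAR_CONSTANT, ErythemalComponents
from .solar_geometry import SolarGeometry, SurfaceOrientation, incidence_cosine

__all__ = [
    "TiltedIrradiance",
    "PerezState",
    "relative_air_mass",
    "sky_clearness",
    "sky_brightness",
    "perez_coefficients",
    "perez_state",
    "beam_on_tilt",
    "ground_reflected",
    "perez_sky_diffuse",
    "total_on_tilt",
    "reindl_diffuse_fraction",
]

_DEG = math.pi / 180.0

#: Broadband solar constant, W/m2 (used only by the "broadband" mode).
BROADBAND_SOLAR_CONSTANT = 1367.0

#: Perez et al. all-weather coefficients (f11, f12, f13, f21, f22, f23)
#: per sky-clearness bin.
PEREZ_COEFFICIENTS = (
    (-0.008, 0.588, -0.062, -0.060, 0.072, -0.022),
    (0.130, 0.683, -0.151, -0.019, 0.066, -0.029),
    (0.330, 0.487, -0.221, 0.055, -0.064, -0.026),
    (0.568, 0.187, -0.295, 0.109, -0.152, -0.014),
    (0.873, -0.392, -0.362, 0.226, -0.462, 0.001),
    (1.132, -1.237, -0.412, 0.288, -0.823, 0.056),
    (1.060, -1.600, -0.359, 0.264, -1.127, 0.131),
    (0.678, -0.327, -0.250, 0.156, -1.377, 0.251),
)
_EPS_BIN_EDGES = (1.065, 1.230, 1.500, 1.950, 2.800, 4.500, 6.200)

#: Beam transposition ratio cap and minimum elevation; the geometric ratio
#: cos(incidence)/sin(elevation) diverges at sunrise/sunset.
BEAM_RATIO_CAP = 20.0
MIN_BEAM_ELEVATION_DEG = 1.0


@dataclass(frozen=True)
class PerezState:
    """Sky state entering the anisotropic model."""

    epsilon: float
    delta: float
    f1: float
    f2: float
    air_mass: float
    bin_index: int


@dataclass(frozen=True)
class TiltedIrradiance:
    """The three irradiance components on one oriented surface (W/m2)."""

    beam: float
    sky_diffuse: float
    ground_reflected: float

    @property
    def total(self) -> float:
        return self.beam + self.sky_diffuse + self.ground_reflected

    @property
    def shares(self) -> dict[str, float]:
        """Fractional contribution of each component to the total."""
        t = self.total
        if t == 0.0:
            return {"beam": 0.0, "sky_diffuse": 0.0, "ground_reflected": 0.0}
        return {
            "beam": self.beam / t,
            "sky_diffuse": self.sky_diffuse / t,
            "ground_reflected": self.ground_reflected / t,
        }


def relative_air_mass(zenith: float) -> float:
    """Kasten-Young relative optical air mass (dimensionless)."""
    if zenith >= 90.0:
        return float("inf")
    return 1.0 / (math.cos(zenith * _DEG) + 0.50572 * (96.07995 - zenith) ** -1.6364)


def sky_clearness(diffuse_h: float, direct_normal: float, zenith: float) -> float:
    """Perez sky-clearness parameter epsilon (>= 1)."""
    z3 = 1.041 * (zenith * _DEG) ** 3
    return ((diffuse_h + direct_normal) / diffuse_h + z3) / (1.0 + z3)


def sky_brightness(air_mass: float, diffuse_h: float, extra_normal: float) -> float:
    """Perez sky-brightness parameter Delta (>= 0)."""
    return air_mass * diffuse_h / extra_normal


def perez_coefficients(epsilon: float, delta: float, zenith: float) -> tuple[float, float, int]:
    """Circumsolar (F1, clamped >= 0) and horizon (F2) brightening
    coefficients, plus the clearness bin used."""
    bin_index = 0
    for edge in _EPS_BIN_EDGES:
        if epsilon >= edge:
            bin_index += 1
    f11, f12, f13, f21, f22, f23 = PEREZ_COEFFICIENTS[bin_index]
    z = zenith * _DEG
    f1 = max(0.0, f11 + f12 * delta + f13 * z)
    f2 = f21 + f22 * delta + f23 * z
    return f1, f2, bin_index


def reindl_diffuse_fraction(clearness_broadband: float, elevation: float) -> float:
    """Reindl et al. broadband diffuse fraction from the clearness index
    k_t and the solar elevation (degrees)."""
    kt = clearness_broadband
    s = math.sin(elevation * _DEG)
    if kt <= 0.3:
        return min(1.0, 1.020 - 0.254 * kt + 0.0123 * s)
    if kt < 0.78:
        return min(0.97, max(0.1, 1.400 - 1.749 * kt + 0.177 * s))
    return max(0.1, 0.486 * kt - 0.182 * s)


def perez_state(
    components: ErythemalComponents,
    geom: SolarGeometry,
    eh: float | None = None,
    mode: str = "erythemal",
) -> PerezState:
    """Evaluate the Perez sky state in the requested band.

    ``mode='erythemal'`` uses the erythemal components; ``mode='broadband'``
    requires ``eh`` (total horizontal irradiance, W/m2) and splits it with
    the Reindl correlations.
    """
    if mode not in ("erythemal", "broadband"):
        raise ValueError(f"unknown Perez parameterization mode: {mode!r}")
    m = relative_air_mass(geom.zenith)
    cz = math.cos(geom.zenith * _DEG)
    if mode == "broadband":
        if eh is None:
            raise ValueError("broadband mode needs the total horizontal irradiance eh")
        extra_normal = BROADBAND_SOLAR_CONSTANT * geom.eccentricity
        kt = eh / (extra_normal * cz)
        diffuse_h = eh * reindl_diffuse_fraction(kt, geom.elevation)
        direct_normal = (eh - diffuse_h) / cz
    else:
        extra_normal = ERYTHEMAL_SOLAR_CONSTANT * geom.eccentricity
        diffuse_h = components.diffuse
        direct_normal = components.direct / cz
    if diffuse_h <= 0.0:
        return PerezState(1.0, 0.0, 0.0, 0.0, m, 0)
    eps = sky_clearness(diffuse_h, direct_normal, geom.zenith)
    delta = sky_brightness(m, diffuse_h, extra_normal)
    f1, f2, bin_index = perez_coefficients(eps, delta, geom.zenith)
    return PerezState(eps, delta, f1, f2, m, bin_index)


def beam_on_tilt(direct_h: float, cosinc: float, elevation: float) -> float:
    """Beam component on the tilted plane, I_er,bh * cos(inc)/sin(alpha).

    Zero when the sun is behind the surface (cos inc <= 0) or below
    ~1 degree of elevation; the geometric ratio is capped to bound the
    sunrise/sunset divergence.
    """
    if elevation <= MIN_BEAM_ELEVATION_DEG or cosinc <= 0.0:
        return 0.0
    ratio = min(BEAM_RATIO_CAP, cosinc / math.sin(elevation * _DEG))
    return direct_h * ratio


def ground_reflected(ierh: float, albedo: float, tilt: float) -> float:
    """Ground-reflected component I_er,h * rho_UV * (1 - cos beta)/2.

    Assumes unobstructed horizontal ground of unlimited extent.
    """
    if not 0.0 <= albedo <= 1.0:
        raise ValueError(f"albedo out of [0, 1]: {albedo}")
    if not 0.0 <= tilt <= 180.0:
        raise ValueError(f"tilt out of range: {tilt}")
    return ierh * albedo * (1.0 - math.cos(tilt * _DEG)) / 2.0


def perez_sky_diffuse(
    components: ErythemalComponents,
    geom: SolarGeometry,
    surface: SurfaceOrientation,
    eh: float | None = None,
    mode: str = "erythemal",
    coefficients: tuple[float, float] | None = None,
) -> float:
    """Anisotropic sky-diffuse component on the tilted plane.

    ``coefficients`` overrides (F1, F2), e.g. (0, 0) forces the isotropic
    limit. For a horizontal surface the result is exactly the horizontal
    diffuse irradiance.
    """
    if components.diffuse <= 0.0:
        return 0.0
    if coefficients is None:
        state = perez_state(components, geom, eh=eh, mode=mode)
        f1, f2 = state.f1, state.f2
    else:
        f1, f2 = coefficients
    beta = surface.tilt * _DEG
    a = max(0.0, incidence_cosine(geom, surface))
    b = max(math.cos(85.0 * _DEG), math.cos(geom.zenith * _DEG))
    value = components.diffuse * (
        (1.0 - f1) * (1.0 + math.cos(beta)) / 2.0 + f1 * a / b + f2 * math.sin(beta)
    )
    return max(0.0, value)


def total_on_tilt(
    components: ErythemalComponents,
    geom: SolarGeometry,
    surface: SurfaceOrientation,
    albedo: float,
    eh: float | None = None,
    mode: str = "erythemal",
) -> TiltedIrradiance:
    """All three components and their sum on one oriented surface.

    With the sun at or below the horizon every component is zero.
    """
    if not geom.sun_up:
        return TiltedIrradiance(0.0, 0.0, 0.0)
    cosinc = incidence_cosine(geom, surface)
    return TiltedIrradiance(
        beam=beam_on_tilt(components.direct, cosinc, geom.elevation),
        sky_diffuse=perez_sky_diffuse(components, geom, surface, eh=eh, mode=mode),
        ground_reflected=ground_reflected(components.global_horizontal, albedo, surface.tilt),
    )
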