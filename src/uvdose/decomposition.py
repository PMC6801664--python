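"""Decomposition of horizontal erythemal irradiance into diffuse and direct.

The split uses the erythemal clearness index k_UV,er — the ratio of the
ground-level erythemal horizontal irradiance to its extraterrestrial
counterpart — together with the solar zenith angle and the total ozone
column (TOC, Dobson units):

    k_UV,er   = I_er,h / (I_TOP * c_d * cos(theta))
    f_diffuse = 1.20 - 35.4 k_UV,er + 0.50 cos(theta) - 1.12e-3 TOC
    I_er,dh   = I_er,h * f_diffuse,      I_er,bh = I_er,h - I_er,dh

where I_TOP = 14.83 W/m2 is the erythemally weighted UV solar constant.
The raw diffuse fraction can leave [0, 1] at extreme clearness or ozone;
it is clipped (with a log warning) so that non-negativity and the exact
conservation I_er,dh + I_er,bh = I_er,h always hold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

__all__ = [
    "ERYTHEMAL_SOLAR_CONSTANT",
    "ErythemalComponents",
    "SunBelowHorizonError",
    "clearness_index",
    "diffuse_fraction",
    "split",
    "decompose",
]

log = logging.getLogger(__name__)

#: Erythemally weighted UV solar constant, W/m2.
ERYTHEMAL_SOLAR_CONSTANT = 14.83

#: Sanity window for the total ozone column, Dobson units.
TOC_SANITY_DU = (100.0, 600.0)


class SunBelowHorizonError(ValueError):
    """Raised when a quantity that divides by cos(zenith) is requested with
    the sun at or below the horizon; callers should short-circuit to zero
    irradiance instead."""


@dataclass(frozen=True)
class ErythemalComponents:
    """Horizontal erythemal irradiance split into diffuse and direct parts."""

    global_horizontal: float
    toc: float
    clearness: float
    diffuse: float
    direct: float

    def __post_init__(self) -> None:
        if self.global_horizontal < 0 or self.diffuse < 0 or self.direct < 0:
            raise ValueError("irradiances must be non-negative")


def clearness_index(ierh: float, eccentricity: float, zenith: float) -> float:
    """Erythemal clearness index k_UV,er, clipped to [0, 1].

    Raises :class:`SunBelowHorizonError` for zenith >= 90 degrees.
    """
    if ierh < 0:
        raise ValueError(f"negative erythemal irradiance: {ierh}")
    if zenith >= 90.0:
        raise SunBelowHorizonError(f"zenith {zenith} >= 90 deg")
    k = ierh / (ERYTHEMAL_SOLAR_CONSTANT * eccentricity * math.cos(zenith * math.pi / 180.0))
    return min(1.0, max(0.0, k))


def diffuse_fraction(clearness: float, zenith: float, toc: float) -> float:
    """Diffuse fraction of the horizontal erythemal irradiance.

    Clipped to [0, 1]; values outside the raw correlation's physical range
    and a TOC outside the sanity window are logged, not fatal.
    """
    if zenith >= 90.0:
        raise SunBelowHorizonError(f"zenith {zenith} >= 90 deg")
    if not TOC_SANITY_DU[0] <= toc <= TOC_SANITY_DU[1]:
        log.warning("TOC %.1f DU outside sanity window %s", toc, TOC_SANITY_DU)
    raw = 1.20 - 35.4 * clearness + 0.50 * math.cos(zenith * math.pi / 180.0) - 1.12e-3 * toc
    if raw < 0.0 or raw > 1.0:
        log.warning("diffuse fraction %.3f outside [0, 1]; clipping", raw)
    return min(1.0, max(0.0, raw))


def split(ierh: float, fraction: float, toc: float = float("nan"),
          clearness: float = float("nan")) -> ErythemalComponents:
    """Apply a diffuse fraction to the horizontal erythemal irradiance.

    Conservation (diffuse + direct = global) is exact by construction.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction out of [0, 1]: {fraction}")
    diffuse = ierh * fraction
    return ErythemalComponents(
        global_horizontal=ierh,
        toc=toc,
        clearness=clearness,
        diffuse=diffuse,
        direct=ierh - diffuse,
    )


def decompose(ierh: float, eccentricity: float, zenith: float, toc: float) -> ErythemalComponents:
    """Full chain: clearness index -> diffuse fraction -> split.

    With the sun at or below the horizon all components are zero.
    """
    if zenith >= 90.0 or ierh == 0.0:
        return ErythemalComponents(ierh if zenith < 90.0 else 0.0, toc, 0.0, 0.0, 0.0)
    k = clearness_index(ierh, eccentricity, zenith)
    f = diffuse_fraction(k, zenith, toc)
    return split(ierh, f, toc=toc, clearness=k)
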