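"""Radiant exposure, SED conversion and phototype risk assessment.

U_A = I_A * dt integrates tilted irradiance into an erythemal radiant
exposure (J/m2); one Standard Erythemal Dose (SED) is 100 J/m2. The dose is
compared against the Minimal Erythema Dose (MED) of the six Fitzpatrick
phototypes; the precautionary lower bound of each phototype's MED range is
used, so a flagged exceedance errs on the safe side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "JOULES_PER_SED",
    "ExposureDose",
    "phototype_table",
    "radiant_exposure",
    "to_sed",
    "integrate_series",
    "med_assessment",
    "altitude_adjust",
    "uv_index",
]

JOULES_PER_SED = 100.0

#: WHO UV-index scale factor, m2/W.
UVI_SCALE = 40.0

#: UV exposure increase per kilometre of altitude.
ALTITUDE_RATE_PER_KM = 0.08


@dataclass(frozen=True)
class ExposureDose:
    """Radiant exposure over one duration."""

    ua: float
    duration: float

    def __post_init__(self) -> None:
        if self.ua < 0:
            raise ValueError("radiant exposure must be non-negative")

    @property
    def sed(self) -> float:
        return self.ua / JOULES_PER_SED


def phototype_table() -> pd.DataFrame:
    """Fitzpatrick phototypes I-VI with cutaneous response, cancer-risk
    label and (precautionary lower-bound) MED in J/m2."""
    with resources.files("uvdose.data").joinpath("table1_phototypes.csv").open() as fh:
        return pd.read_csv(fh)


def radiant_exposure(ia: float, duration: float) -> float:
    """U_A = I_A * dt (J/m2) for a constant irradiance over the exposure."""
    if duration <= 0:
        raise ValueError(f"non-positive exposure duration: {duration}")
    return ia * duration


def to_sed(ua: float) -> float:
    """Convert a radiant exposure (J/m2) to Standard Erythemal Doses."""
    if ua < 0:
        raise ValueError(f"negative radiant exposure: {ua}")
    return ua / JOULES_PER_SED


def integrate_series(
    times_s,
    irradiances,
    window: float,
    gap_tolerance: float | None = None,
) -> pd.DataFrame:
    """Rectangle-rule dose integration of an irradiance series into windows.

    ``times_s``: sample times in seconds (uniformly spaced, time-ordered);
    ``window``: window length in seconds, a multiple of the sampling step.
    Each sample contributes irradiance * step to the window containing its
    start. Gaps larger than the step raise unless ``gap_tolerance`` allows
    them.

    Returns a frame with window start times, U_A and SED per window.
    """
    t = list(times_s)
    v = list(irradiances)
    if len(t) != len(v) or len(t) < 2:
        raise ValueError("need two equal-length, >=2-sample sequences")
    steps = [b - a for a, b in zip(t, t[1:])]
    if any(s <= 0 for s in steps):
        raise ValueError("sample times must be strictly increasing")
    step = min(steps)
    tol = step + (gap_tolerance if gap_tolerance is not None else step * 1e-6)
    if any(s > tol for s in steps):
        raise ValueError("gap in the series exceeds the configured tolerance")
    if abs(window / step - round(window / step)) > 1e-9 or window <= 0:
        raise ValueError("window must be a positive multiple of the sampling step")
    rows: dict[float, float] = {}
    for ti, vi in zip(t, v):
        w0 = t[0] + math.floor((ti - t[0]) / window) * window
        rows[w0] = rows.get(w0, 0.0) + vi * step
    out = pd.DataFrame(sorted(rows.items()), columns=["window_start_s", "ua_j_m2"])
    out["sed"] = out["ua_j_m2"] / JOULES_PER_SED
    return out


def med_assessment(ua: float, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Dose-to-MED ratio and exceedance flag per phototype.

    A ratio >= 1 means the exposure reaches the minimal erythema dose of
    that phototype.
    """
    if table is None:
        table = phototype_table()
    out = table.copy()
    out["ratio"] = ua / out["med_j_m2"]
    out["exceeded"] = out["ratio"] >= 1.0
    return out


def altitude_adjust(value: float, altitude_delta_km: float) -> float:
    """Linear altitude scaling: +8% of UV exposure per kilometre.

    Applies identically to an irradiance or a dose. Off by default in the
    dose chain; apply explicitly where wanted.
    """
    if altitude_delta_km < -0.5:
        raise ValueError(f"altitude delta below model range: {altitude_delta_km}")
    return value * (1.0 + ALTITUDE_RATE_PER_KM * altitude_delta_km)


def uv_index(ierh: float) -> float:
    """WHO UV index: 40 m2/W times the horizontal erythemal irradiance.

    Convenience output only; not part of the dose chain.
    """
    return UVI_SCALE * ierh
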