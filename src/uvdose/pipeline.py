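"""End-to-end dose chain: conditions in, per-surface exposure out.

Ties together solar geometry, the diffuse/direct decomposition, the tilted
transposition and the dose bookkeeping, for a single instant or for a
time series read from a CSV-like frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from . import decomposition, dose_assessment, transposition
from .solar_geometry import Instant, Site, SurfaceOrientation, incidence_cosine, solar_position

__all__ = ["Conditions", "point_exposure", "series_exposure"]


@dataclass(frozen=True)
class Conditions:
    """Everything the chain needs at one instant."""

    site: Site
    instant: Instant
    ierh: float
    toc: float
    albedo: float
    eh: float | None = None
    sky_mode: str = "erythemal"


def point_exposure(conditions: Conditions, surface: SurfaceOrientation, duration: float) -> dict:
    """Full chain for one surface and one instant.

    The irradiance is held constant over ``duration`` seconds (the
    convention of the hourly worked examples). Returns every intermediate
    quantity so that tables and reports can be assembled from it.
    """
    geom = solar_position(conditions.site, conditions.instant)
    comps = decomposition.decompose(
        conditions.ierh if geom.sun_up else 0.0, geom.eccentricity, geom.zenith, conditions.toc
    )
    tilted = transposition.total_on_tilt(
        comps, geom, surface, conditions.albedo, eh=conditions.eh, mode=conditions.sky_mode
    )
    ua = tilted.total * duration
    return {
        "tilt": surface.tilt,
        "azimuth": surface.azimuth,
        "zenith": geom.zenith,
        "elevation": geom.elevation,
        "eccentricity": geom.eccentricity,
        "clearness": comps.clearness,
        "ierh": comps.global_horizontal,
        "ierdh": comps.diffuse,
        "ierbh": comps.direct,
        "cos_incidence": incidence_cosine(geom, surface) if geom.sun_up else 0.0,
        "iba": tilted.beam,
        "idas": tilted.sky_diffuse,
        "idag": tilted.ground_reflected,
        "ia": tilted.total,
        "ua": ua,
        "sed": dose_assessment.to_sed(ua),
        "uvi": dose_assessment.uv_index(comps.global_horizontal),
    }


def series_exposure(
    frame: pd.DataFrame,
    site: Site,
    surface: SurfaceOrientation,
    toc: float,
    albedo: float,
    utc_offset: float = 0.0,
    sky_mode: str = "erythemal",
    duration: float | None = None,
) -> pd.DataFrame:
    """Run the chain over a time series.

    ``frame`` needs columns ``day_of_year``, ``hour`` (clock time, decimal
    hours) and ``ierh``; optional per-row ``toc`` and ``eh`` override the
    scalar arguments. ``duration`` is the per-sample integration time in
    seconds (defaults to the sampling step).
    """
    required = {"day_of_year", "hour", "ierh"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"series frame lacks columns: {sorted(missing)}")
    if duration is None:
        hours = frame["hour"].to_numpy()
        if len(hours) < 2:
            raise ValueError("cannot infer the sampling step from a single row")
        duration = float(min(b - a for a, b in zip(hours, hours[1:]))) * 3600.0
    rows = []
    for _, rec in frame.iterrows():
        cond = Conditions(
            site=site,
            instant=Instant(int(rec["day_of_year"]), float(rec["hour"]),
                            convention="clock", utc_offset=utc_offset),
            ierh=float(rec["ierh"]),
            toc=float(rec["toc"]) if "toc" in frame.columns else toc,
            albedo=albedo,
            eh=float(rec["eh"]) if "eh" in frame.columns and pd.notna(rec.get("eh")) else None,
            sky_mode=sky_mode,
        )
        out = point_exposure(cond, surface, duration)
        out["hour"] = float(rec["hour"])
        rows.append(out)
    return pd.DataFrame(rows)
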