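"""Body districts as sets of oriented planes tied to a worker's posture.

Head, torso, arms and legs are approximated as prisms whose faces are flat
oriented surfaces; the dose chain is run face by face and the district's
exposure is summarized by its most exposed face. A single worker heading
rotates all face azimuths together (heading 0 = facing south).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dose_assessment import med_assessment
from .pipeline import Conditions, point_exposure
from .solar_geometry import SurfaceOrientation

__all__ = ["DistrictSurfaceSet", "preset_posture", "district_dose_report"]


@dataclass(frozen=True)
class DistrictSurfaceSet:
    """One body district: a named set of (face label, orientation) pairs."""

    district: str
    faces: tuple[tuple[str, SurfaceOrientation], ...]
    posture: str = "custom"

    def __post_init__(self) -> None:
        if not self.faces:
            raise ValueError("a district needs at least one face")


def _wrap(azimuth: float) -> float:
    a = (azimuth + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _district(name, posture, *faces):
    return DistrictSurfaceSet(
        district=name,
        posture=posture,
        faces=tuple((label, SurfaceOrientation(tilt, _wrap(az))) for label, tilt, az in faces),
    )


def preset_posture(name: str, heading: float = 0.0) -> list[DistrictSurfaceSet]:
    """Built-in postures.

    ``standing``: vertical torso front/back, vertical arms, horizontal head
    top. ``bending``: torso faces tilted to 45 degrees (back up-facing).
    Face azimuths are the worker heading rotated by each face's offset.
    """
    if name == "standing":
        return [
            _district("head", name, ("head-top", 0.0, 0.0)),
            _district(
                "torso", name,
                ("torso-front", 90.0, heading),
                ("torso-back", 90.0, heading + 180.0),
            ),
            _district(
                "arm", name,
                ("arm-left", 90.0, heading - 90.0),
                ("arm-right", 90.0, heading + 90.0),
            ),
        ]
    if name == "bending":
        return [
            _district("head", name, ("head-top", 45.0, heading)),
            _district(
                "torso", name,
                ("torso-front", 45.0, heading),
                ("torso-back", 45.0, heading + 180.0),
            ),
            _district(
                "arm", name,
                ("arm-left", 90.0, heading - 90.0),
                ("arm-right", 90.0, heading + 90.0),
            ),
        ]
    raise ValueError(f"unknown posture preset: {name!r}")


def district_dose_report(
    sets: list[DistrictSurfaceSet],
    conditions: Conditions,
    duration: float,
) -> pd.DataFrame:
    """Per-face doses for every district, with the most exposed face flagged.

    Returns one row per face: district, posture, face label, orientation,
    I_A, U_A, SED, ``most_exposed`` (True for the district's maximum-dose
    face) and the lowest phototype whose MED the face's dose reaches.
    """
    meds = med_assessment(0.0)[["phototype", "med_j_m2"]]
    rows = []
    for dset in sets:
        for label, surface in dset.faces:
            rec = point_exposure(conditions, surface, duration)
            reached = meds[meds["med_j_m2"] <= rec["ua"]]
            rows.append(
                {
                    "district": dset.district,
                    "posture": dset.posture,
                    "face": label,
                    "tilt": surface.tilt,
                    "azimuth": surface.azimuth,
                    "ia": rec["ia"],
                    "ua": rec["ua"],
                    "sed": rec["sed"],
                    "med_exceeded_up_to": reached["phototype"].iloc[-1] if len(reached) else "",
                }
            )
    out = pd.DataFrame(rows)
    out["most_exposed"] = False
    for district, group in out.groupby("district"):
        out.loc[group["ua"].idxmax(), "most_exposed"] = True
    return out
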