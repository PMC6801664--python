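"""Erythemal dose versus surface tilt, facing south and north.

Same clear June noon in Pisa as vertical_walls_at_noon.py. Sweeping the
tilt shows the trade-off between beam interception (maximal when the
surface faces the sun squarely) and the shrinking view of the sky dome.
"""

from uvdose import Conditions, Instant, Site, SurfaceOrientation, point_exposure

conditions = Conditions(
    site=Site(43.72, 10.39, 4.0),
    instant=Instant(172, 12.0, convention="solar"),
    ierh=0.214,
    toc=329.0,
    albedo=0.011,
)

print("tilt   U_A south  beam-share   U_A north")
best = (0.0, 0.0)
for beta in [0, 15, 23.4, 30, 45, 60, 75, 90]:
    s = point_exposure(conditions, SurfaceOrientation(beta, 0.0), 3600.0)
    n = point_exposure(conditions, SurfaceOrientation(beta, 180.0), 3600.0)
    share = 100 * s["iba"] / s["ia"]
    print(f"{beta:5.1f} {s['ua']:9.0f} {share:10.0f}% {n['ua']:10.0f}")
    if s["ua"] > best[1]:
        best = (beta, s["ua"])

print(f"\nMost exposed south tilt: {best[0]:.1f} deg with {best[1]:.0f} J/m2 "
      f"({best[1] / 100:.1f} SED) in the hour - tilting towards the sun beats "
      "both the horizontal and the vertical.")
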