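# uvdose

Erythemal UV irradiance and dose on tilted surfaces — and on the body
districts of outdoor workers.

Sunburn risk is governed by the *erythemally weighted* UV irradiance a
surface receives, not by the horizontal value that radiometers and
satellite products report. Agricultural workers, builders, lifeguards and
ski guides expose faces, torsos, arms — planes of every tilt β and
orientation γ. `uvdose` converts a horizontal erythemal irradiance
I<sub>er,h</sub> (W/m²), a total ozone column (TOC, Dobson units) and a UV
ground albedo ρ<sub>UV</sub> into the irradiance and dose on any oriented
plane, anywhere on Earth, and compares the dose against the minimal
erythema dose (MED) of the six Fitzpatrick skin phototypes.

## The model

1. **Solar geometry** — declination, hour angle, zenith θ, solar azimuth
   and surface incidence cosine from a Meeus-grade ephemeris; clock → solar
   time via longitude and the equation of time.
2. **Decomposition** — the erythemal clearness index
   k<sub>UV,er</sub> = I<sub>er,h</sub> / (14.83 · c<sub>d</sub> · cos θ)
   (14.83 W/m² is the erythemal UV solar constant, c<sub>d</sub> the
   Earth–Sun eccentricity factor) feeds the ozone-aware diffuse fraction
   f = 1.20 − 35.4 k<sub>UV,er</sub> + 0.50 cos θ − 1.12·10⁻³ TOC,
   splitting I<sub>er,h</sub> into diffuse I<sub>er,dh</sub> and direct
   I<sub>er,bh</sub> with exact conservation.
3. **Transposition** — on a plane (β, γ):
   I<sub>A</sub> = I<sub>bA</sub> + I<sub>dA,s</sub> + I<sub>dA,g</sub>, with
   beam I<sub>bA</sub> = I<sub>er,bh</sub> · cos ϑ / sin α, ground-reflected
   I<sub>dA,g</sub> = I<sub>er,h</sub> · ρ<sub>UV</sub> · (1 − cos β)/2, and
   the sky-diffuse term from the Perez all-weather anisotropic model
   (circumsolar F1, horizon brightening F2, binned by sky clearness ε and
   brightness Δ — evaluated in-band by default, or from a broadband
   irradiance E<sub>h</sub> via the Reindl split).
4. **Dose** — U<sub>A</sub> = I<sub>A</sub> · Δt (J/m²), SED = U<sub>A</sub>/100,
   per-phototype MED ratios (precautionary lower-bound MEDs, 150–900 J/m²),
   optional +8 %/km altitude scaling, and the WHO UV index as a convenience.
5. **Body districts** — head, torso and arms as prism faces tied to a
   posture preset (`standing`, `bending`) and a worker heading; the report
   flags each district's most exposed face.

## Worked example

One hour centred on solar noon at the June solstice in Pisa (43.72° N),
clear sky: I<sub>er,h</sub> = 0.214 W/m², TOC = 329 DU, grass albedo 0.011
(`examples/vertical_walls_at_noon.py`):

```
wall    cos(inc)  beam    sky     ground  I_A     U_A[J/m2]  SED
south     0.347   0.021   0.081  0.0012   0.103       370   3.7
west      0.000   0.000   0.066  0.0012   0.067       241   2.4
east      0.000   0.000   0.066  0.0012   0.067       241   2.4
north    -0.347   0.000   0.066  0.0012   0.067       241   2.4

south wall: 3.7 SED in one hour; reaches the MED of phototypes I, II, III.
```

Only the south wall intercepts beam radiation at noon (cos ϑ = 0.347); the
east, west and north walls receive identical sky-diffuse and
ground-reflected irradiance, so their doses coincide — 3.7 SED in a single
hour is already past the sunburn threshold for sensitive skin. Sweeping the
tilt (`examples/tilt_sweep.py`) shows the most exposed south-facing tilt is
β ≈ 15° with 791 J/m² in the hour; `examples/worker_day.py` runs a standing
worker through a synthetic clear morning, and
`examples/campaign_validation.py` confronts the chain with a packaged
three-site field campaign (94 measured doses): sun-facing and horizontal
surfaces — the ones that carry the overexposure risk — agree to 7 % mean
absolute error (doses > 40 J/m²), while shaded verticals are overpredicted
(see the methods note).

A thin CLI wraps the same chain:

```sh
uvdose point --lat 43.72 --lon 10.39 --day 172 --time 12 --beta 90 \
       --gamma 0 --toc 329 --albedo 0.011 --ierh 0.214
uvdose validate
```

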