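# Methods

## Scope and model chain

`uvdose` computes erythemally weighted UV irradiance and radiant exposure
(dose) on arbitrarily oriented planes from three inputs a practitioner can
actually obtain: the horizontal erythemal irradiance I_er,h (measured, or
from a radiative-transfer product), the total ozone column (TOC, DU) and a
UV-band ground albedo. The chain is

    solar geometry -> diffuse/direct decomposition -> tilted transposition
    -> dose integration -> phototype MED assessment,

with body districts (head, torso, arms) represented as sets of oriented
prism faces so the same chain yields a per-face worker exposure report.

## Solar geometry

Declination and the equation of time come from a Meeus-grade low-precision
ephemeris (the NOAA solar-calculator algorithm), anchored to a fixed
reference year (2019, the campaign year of the validation fixtures);
year-to-year differences (< 0.25 deg) are negligible at every tolerance
used here. Classic single-sine formulas were considered and rejected: their
worst-case declination error (~1.1 deg against an independent ephemeris)
breaks the 0.3 deg solar-position agreement this package promises, which
the tests verify against an independently coded USNO Astronomical Almanac
approximation. Azimuths are measured from south (east negative, west
positive, north 180), all interface angles in degrees, day-of-year 1-based;
leap day 366 is accepted (sub-printed-precision effect). The Earth-Sun
eccentricity factor keeps the classic day-angle cosine form
c_d = 1 + 0.033 cos(2 pi n/365), which the decomposition chain validates
end-to-end (it reproduces the reference diffuse/direct split to the printed
0.001 W/m2); the ephemeris cross-check holds it within 0.005 of (1/R)^2.

## Decomposition

The erythemal clearness index k_UV,er = I_er,h / (14.83 c_d cos theta)
uses the erythemal solar constant 14.83 W/m2. The diffuse fraction

    f = 1.20 - 35.4 k_UV,er + 0.50 cos theta - 1.12e-3 TOC

is clipped to [0, 1] with a log warning: the correlation can leave the
physical range at extreme clearness or ozone, and clipping preserves
non-negativity and conservation (I_er,dh + I_er,bh = I_er,h, exact up to
IEEE rounding; asserted at 1e-12 relative). TOC outside [100, 600] DU
warns but computes. Zenith >= 90 deg short-circuits the whole chain to
zero irradiance rather than dividing by cos theta.

## Transposition

Beam uses the geometric ratio cos(incidence)/sin(elevation), zeroed when
the sun is behind the surface or below 1 deg elevation and capped at 20 to
bound the sunrise/sunset divergence (the cap is inactive in every packaged
scenario; elevations there are 31-70 deg). Ground reflection is the
isotropic view-factor term I_er,h rho_UV (1 - cos beta)/2, assuming
unobstructed horizontal ground. Sky diffuse uses the Perez all-weather
anisotropic model with the published 8-bin coefficient table, Kasten-Young
air mass, F1 clamped >= 0 and b = max(cos 85deg, cos zenith).

Two parameterization modes set the band in which sky clearness epsilon and
brightness Delta are evaluated:

* `erythemal` (default): from the erythemal components themselves against
  the 14.83 W/m2 constant. Self-contained; but note that the erythemal sky
  is diffuse-dominated even under clear skies, so epsilon lands in the
  "intermediate" bins and the anisotropy is mild.
* `broadband`: epsilon/Delta from a measured total irradiance E_h, split
  by the Reindl correlations against the 1367 W/m2 constant. A clear sky
  is then classified as clear (epsilon > 2.8 in the packaged worked
  example), giving a strongly circumsolar sky whose F1/F2 are applied to
  the erythemal diffuse.

The default follows the self-contained mode; the campaign fixtures carry
E_h so either mode can be exercised there.

## Dose and risk

U_A = I_A dt with irradiance held constant over the exposure (the
worked-example convention: 0.214 W/m2 x 3600 s = 770 J/m2 on the
horizontal); series are integrated by the left-endpoint rectangle rule at
the native sampling step (60 s samples into 600 s windows in the campaign;
trapezoid differences are below printed precision). 1 SED = 100 J/m2
exactly. MED thresholds are the precautionary lower bounds per phototype
(150, 250, 300, 400, 600, 900 J/m2). The +8%/km altitude scaling is a
separate, explicitly invoked linear operation, and the WHO UV index
(40 m2/W x I_er,h) is a labelled convenience — neither enters the dose
chain.

## Body districts

Districts are flat prism faces (no cylindrical receptors, no clothing or
inter-limb shading): standing = vertical torso front/back and arms plus a
horizontal head top; bending tilts the torso faces to 45 deg. One heading
angle rotates all azimuths. Face areas are irrelevant for dose per unit
area and are omitted.

## Validation fixtures and campaign reproduction

The packaged fixtures transcribe the reference study's tables: phototypes,
the worked-example inputs and printed results, and a three-site Italian
field campaign (Rome 2019-02-21, Guadagnolo 2019-02-25, Pisa 2019-05-16;
94 doses per 600 s on horizontal, tilted and vertical surfaces, plus a
broadband irradiance series per site). Choices the source leaves open:

* **Clock times.** The campaign table labels its times "GMT+1", but the
  printed zenith angles of all three sites — and the timing of the
  measured Pisa horizontal-dose peak (~13:15) — are consistent only with a
  +2 h offset (civil daylight time for Pisa in May). The fixtures store
  +2 h so the published geometry reproduces.
* **Rome coordinates.** Two coordinate pairs appear in the source; the
  fixtures default to the pair stated as algorithm input (41.54 N,
  12.28 E) and carry the alternative (41.89 N, 12.49 E) alongside.
* **Campaign I_er,h.** The study does not state the horizontal erythemal
  irradiance series it fed its calculations (its own horizontal
  predictions do not match its measured horizontal doses, so it was not
  the measurement). This package uses the defensible choice: the measured
  horizontal dose / 600 s at each (site, time); Rome, which measured the
  horizontal only once, is scaled by the broadband series ratio
  E_h(t)/E_h(t0). With that choice the beta=0 predictions close exactly
  on the measurements by construction, which is the correct behaviour of
  a transposition chain, not a fit.
* **MAE definition.** "Mean absolute error" in percent is read as the mean
  of |calculated - measured| / measured x 100 — the only reading
  consistent with the percentage units and with the study's own median
  statistic, which this definition reproduces exactly (50% of records
  below 10% deviation).

## Known discrepancies with the reference study (why some acceptance checks are red)

Every upstream quantity reproduces at printed precision: clearness index,
diffuse/direct split (0.158/0.056 W/m2), incidence cosines for south
azimuths, beam components (including the 0.060 W/m2 maximum at the
sun-orthogonal tilt), ground-reflected values to 1e-6 W/m2, and the
horizontal closure I_A(beta=0) = I_er,h. Three classes of published values
do not reproduce, and the analysis says they cannot:

1. **Tilted sky diffuse.** The study prints I_dA,s ~ I_er,dh (0.159 vs
   0.158 W/m2) even on vertical surfaces, for both the sun-facing and the
   shaded azimuth. No evaluation of the cited anisotropic model yields
   this: the in-band mode gives 0.081 W/m2 on the south vertical, the
   broadband mode 0.087, the isotropic limit 0.079 — all about half the
   printed value, because a vertical plane sees half the sky dome. Solving
   the model's functional form for (F1, F2) against the printed south and
   north tilt sweeps has no solution: the printed south-north difference
   scales as cos(beta), impossible for any circumsolar term linear in the
   incidence cosine (whose azimuth dependence scales as sin(beta)), and
   the printed north sweep is discontinuous at beta -> 0. The printed
   worked-example doses downstream (652, 576, 814 J/m2) inherit this.
2. **North-facing incidence.** The study's north-sweep incidence cosines
   are the negated south values (e.g. -0.996 at beta = 15 deg), but the
   correct geometry gives cos(beta + theta) = +0.82 — a gently
   north-tilted surface at 20 deg solar zenith *does* intercept beam. The
   study's "north surfaces receive no direct component" holds only for
   the vertical; its south/north dose ratios (mean 1.5, max 1.9) are
   artifacts of that sign error.
3. **Campaign summary statistics.** Recomputing the study's own two
   printed tables (measured vs calculated doses) gives an overall MAE of
   17.6% where 20% is claimed, and a 75th percentile deviation of 21.7%
   where 18% is claimed; the >40 J/m2 MAE (7.3% vs "7%") and the median
   (<10%) do reproduce. These are arithmetic facts of the printed tables
   under every denominator convention tried.

End-to-end, this package's own campaign predictions agree with the
measurements to 7.3% MAE for doses above 40 J/m2 (the overexposure-relevant
range, dominated by horizontal and sun-facing surfaces where the beam term
leads). Overall MAE is 77%: shaded vertical surfaces are overpredicted
roughly twofold, because the measured erythemal diffuse on shaded verticals
is ~0.1-0.2 of the horizontal diffuse while every configuration of the sky
model yields 0.3-0.6. The measured field data therefore suggest the real
erythemal sky is far more circumsolar than either parameterization of the
model represents; a UV-refitted coefficient set would be the natural
extension. The study's corresponding calculated table implies a sky-diffuse
treatment inconsistent with its own worked examples and is not reproducible
either.

## Synthetic data

`synthetic_clear_sky_series` emulates only the smooth clear-day bell:
I_er,h(t) = peak * (cos zenith(t) / cos zenith_noon)^k (default k = 1.2,
a mild optical-depth steepening), zero below the horizon, with optional
seeded multiplicative Gaussian noise. It does not emulate clouds, cloud
enhancement, aerosol variability or horizon obstruction — tests passing on
it demonstrate the chain's bookkeeping and geometry, not meteorology.

## Numerical choices and limitations

Scalar-float implementation (the problem sizes here are tens of surface
evaluations; vectorization would buy nothing). Degenerate inputs: sun at
zenith returns azimuth 0 by convention; diffuse = 0 skips the sky model;
empty pairings and gapped series raise. Problem sizes in the packaged
runs: 94 campaign records, 18 worked-example surfaces — the full suite and
the acceptance script each run in seconds. Not modelled: horizon
obstruction (the study itself names it as its largest error source at the
mountain site), multi-surface reflections, clothing/sunscreen, cloud
fields, vitamin-D weighting.
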