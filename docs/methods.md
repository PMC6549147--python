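# Methods

This note documents the models implemented in `ventbloom`, the parameter
choices that matter, the design decisions taken where the methodology was
genuinely open, and the limits of what the synthetic-data tests demonstrate.

## Profile processing

**Equation of state.** Potential density anomaly σ₀ is computed with the
EOS-80 formulation (one-atmosphere density polynomial plus the Bryden
adiabatic lapse rate integrated to the surface with the standard
Runge–Kutta scheme). The implementation reproduces the published UNESCO
check values to their printed precision (`tests/test_seawater.py`). TEOS-10
would differ by well under 0.01 kg m⁻³ over the water masses handled here,
far below the 0.03 kg m⁻³ mixed-layer threshold and the 0.2 kg m⁻³
alongstream signal.

**Mixed layer depth.** MLD is the shallowest depth where σ₀ exceeds its
value at 10 m by 0.03 kg m⁻³. The crossing is located by linear
interpolation between the bracketing levels (not the first discrete level
past the threshold) so the result is independent of the vertical grid; the
convention is recorded in output flags. The 10 m reference is interpolated
when the cast brackets it; casts whose shallowest level lies in 10–15 dbar
use that level with a flag; casts starting deeper have undefined MLD.
Pressure in dbar is treated as depth in metres for the MLD and the 25 m
climatology levels (sub-0.5% error above 2000 dbar).

**Quenching correction.** Daytime fluorescence is corrected by replacing
every value shallower than the fluorescence maximum at-or-above the MLD with
that maximum. The correction is applied to raw counts before calibration;
because the calibration is affine with a clamp at the dark value, the two
orders agree whenever counts exceed dark (tested).

**Calibration.** chl = max(counts − dark, 0)·slope·F₄₉₀ with F₄₉₀ = 0.3 by
default, the conservative basin-wide radiometric correction; its reciprocal
(≈ 3.3) is the implied factory-calibration overestimation. Dark and slope
are instrument constants with defaults (47 counts, 0.012 mg m⁻³ count⁻¹) at
the typical order of magnitude of ECO-series fluorometers; negative
dark-corrected values are clamped to zero since concentrations are
non-negative.

**Euphotic depth.** Z_eu(Chl_surf) uses the log–log cubic
log₁₀ Z_eu = 1.524 − 0.436 x − 0.0145 x² + 0.0186 x³, x = log₁₀ Chl_surf,
with coefficients exposed in the configuration. "Surface" chlorophyll is the
mean over the top 10 m (a definition the source methodology leaves open).

**Integration.** Trapezoidal, from the surface (shallowest value extended
upward) to max(MLD, Z_eu), with the endpoint value interpolated.

## Bloom phenology

Cycles start 1 July; a cycle qualifies with ≥ 8 profiles inside
1 November – end of February (29 February in leap years — "early November to
late February" has no other defensible concrete reading; both dates are
configurable). Bins of 20 days are anchored at 1 July so bin edges are
reproducible across floats; the per-bin statistic is the **mean** of
integrated chlorophyll and the magnitude is the max bin mean — the
binned-decorrelation wording admits mean or max per bin; the mean matches
the smoothing intent and is what the recovery tests encode. Bloom typing
uses the precedence island/plateau > ice > ridge > HNLC over configured
masks; the ridge-influence zone is a configured region because no
algorithmic boundary exists for it — classification is reproducible but
configured. Type magnitudes are compared with the tie-corrected
Kruskal–Wallis H test (scipy).

## Eddy kinetic energy

Displacement velocities use the local-tangent conversion at the mean
latitude of each displacement with R = 6371 km. Box statistics use
population (1/n) variances as the time-average overbar; at the > 5-sample
threshold the n vs n−1 difference is below 20% and shrinks as counts grow.
Smoothing uses w = count·exp(−d²/2r²) with r = 100 km ("Gaussian correlation
function" admits exp(−d²/r²) too, which is the same family with a rescaled
radius); the smoothed field is a convex combination of box values, and box
moments are pooled over the whole record in a single pass. Great-circle
distances are haversine.

## Density climatology and alongstream Δσ

Profiles with QC flag 1 are interpolated to 25 dbar levels (0–2000 dbar),
converted to σ₀, and mapped per level with an isotropic Gaussian-weighted
mean (scale 550 km, n_eff floor 0.2); the anisotropic isobath-following and
front-sharpening refinements of full climatological mappings are deliberately
out of scope. The final field is convectively sorted per column (stable
stratification), with the number of adjusted columns recorded.

Sections at 28°E and 38°E are resampled from latitude to dynamic height
using the dh field at each meridian, restricted to the largest monotone
envelope where dh(lat) is non-monotone. Δσ = σ_downstream − σ_upstream on
the shared dh axis: positive values at depth mean denser water at fixed
pressure downstream, i.e. isopycnals shallower downstream. Pseudo-latitude
inverts the sector-mean dh(lat) (isotonic regression applied and flagged if
non-monotone). For synthetic runs dh comes from the generator's prescribed
streamfunction; for real runs it is an input grid — the module never derives
dh from T/S.

## Lagrangian iron delivery

Trajectories integrate dx/dt = u with classical RK4 (6 h step), bilinear in
space and linear in time, degrees↔metres conversion using cos(lat) at every
stage; missing-velocity stages beach the particle at its last valid
position. The contact search runs **backward** from each seed so the first
source contact met is the most recent one; forward re-integration from the
found contact is used as a consistency cross-check in the tests. Sources are
shallow bathymetry (< 500 m, nearest-node test) and the two upwelled-ridge
disks (great-circle membership). Delivery = 100·exp(−age/τ).

The scavenging e-folding time τ is **not** fixed by the source methodology.
The default is τ = 90 days; however, the regime in which 10–30% of source
iron survives 1–2 month transits corresponds to τ ≈ 20–35 days, so τ is a
first-class configuration parameter and the closed-form checks
(`iron_fraction(τ,τ) = e⁻¹`, 10% contour at U·τ·ln 10) hold for any τ; the
test suite exercises them at τ = 20 d so the contour fits inside the
150-day lookback horizon on a compact domain. Seed times within a season
default to every 10 days (the seeding cadence within seasons is otherwise
unspecified).

## Synthetic generators: what they emulate, and what they do not

All generators are pure functions of (parameters, seed); every fixture ships
a machine-readable truth ledger.

* **Float series.** Chl(z,t) = c₀(t)·exp(−z/D) inside a mixed layer of
  prescribed depth (100 m), zero below; c₀(t) Gaussian in time with a
  40-day scale centred 130 days after 1 July (8 November — a bin centre, so
  the 20-day bin mean loses < 2% of the peak), scaled so the vertical
  integral peaks at the prescribed magnitude. D = 300 m gives a
  near-homogeneous mixed-layer profile, as observed in deeply mixed
  Southern Ocean waters. Daytime quenching multiplies values above a
  light-penetration depth of 0.3·MLD by (1 − q): quenching confined to the
  upper mixed layer is precisely the phenomenology the max-above-MLD
  extrapolation corrects — were quenching uniform over the whole mixed
  layer, no within-profile correction could recover it. T/S profiles are
  built by inverting the EOS at fixed salinity so the density threshold is
  crossed exactly at the prescribed MLD. Counts = chl/(F₄₉₀·slope) + dark,
  so factory calibration overestimates truth by 1/F₄₉₀ by construction.
* **Velocity fields.** The solid-body field is exact rotation in the scaled
  plane (X, Y) = ((lon−lon_c)·cos lat_c, lat−lat_c), making the analytic
  orbit circular with known period so integrator error is measured free of
  grid-interpolation error (an analytic-field adapter bypasses the grid).
  The eddy train adds A·(sin, cos)(kx − ωt) to both components: sampled over
  integer periods its time variance is exactly A²/2 per component, so true
  EKE = A²/2.
* **Displacements.** Velocities are mean flow + isotropic Gaussian noise;
  endpoints are built by inverting the same midpoint formula the reader
  uses, and displacement *midpoints* are sampled uniformly so sample
  positions are independent of velocity (binning endpoints or startpoints
  would otherwise select velocities by where particles land — a real
  artifact of displacement-derived velocity atlases that the recovery test
  deliberately excludes).
* **Hydrography.** σ(P, lat, lon) = stratified background + a bounded tanh
  front centred on (a possibly meandering) 50°S + tilt·(lon−28°)/10°·shape(P)
  with shape peaking at 750 dbar, plus noise; T/S by EOS inversion against a
  fixed salinity profile. The meander displaces front and dh field
  identically, so in dh coordinate only the tilt survives — the property the
  alongstream comparison exists to exploit. The sampling band (32–68°S) is
  deliberately much wider than the mapped region: a Gaussian-mean mapping is
  biased wherever its sampling window is truncated within a decorrelation
  scale of field structure, and that bias does not cancel between sections
  when the front moves relative to a narrow window.
* **Tracers.** δ³He Gaussian in depth about 1500 m, amplitude decaying
  exponentially only east (downstream) of the ridge, suppressed toward
  background above a 500 m thermocline (air–sea exchange).
* **Bathymetry.** Gaussian ridge (crest 1400 m) on a 4000 m plain plus a
  < 500 m shelf at the western edge, exercising both source types.

These fixtures validate the *computational chain*, not the geophysics: they
contain no sampling irregularity beyond configurable cadence, no
velocity-field divergence or unresolved submesoscale, no real covariance
between density, dh and velocity, and no instrument drift. Passing tests
therefore demonstrate correct implementation of each operation and of their
composition at realistic parameter values — not that the real-ocean values
would be recovered from real archives.

## Problem sizes and numerics

The default test/acceptance configuration uses one-float seasons of 36
profiles, 10⁴ displacement cycles, 80-step velocity records on ~1° grids,
1800 hydrographic profiles mapped to a 0.5° grid over 20–46°E × 45–55°S at
81 levels, and 13 tracer stations; the full suite runs in well under a
minute of CPU apart from the mapping chain (~10 s). Bisection EOS inversion
is vectorised and converges to 10⁻¹⁰ °C; OI weights below the n_eff floor
(0.2) leave nodes missing rather than extrapolating; linear (never spline)
interpolation is used for sections to keep gridded tracer values inside the
data range; ties in the NPQ maximum resolve to the shallowest level.
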