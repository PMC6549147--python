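# ventbloom

Tools for diagnosing how hydrothermal vents along a mid-ocean ridge can fuel
open-ocean phytoplankton blooms, built for the Southwest Indian Ridge (SWIR)
sector of the Southern Ocean — iron-limited (HNLC) waters where any iron
supply leaves a visible biological imprint.

The package implements the full observational chain as a tested library with
a thin CLI:

* **BGC-Argo profile processing** — fluorescence counts → chlorophyll
  (`chl = max(counts − dark, 0) · slope · F₄₉₀`, with the Southern Ocean
  radiometric correction F₄₉₀ = 0.3), non-photochemical quenching correction
  on daytime casts (the maximum fluorescence above the mixed layer is
  extrapolated to the surface), mixed layer depth from the Δσ₀ = 0.03 kg m⁻³
  threshold at the 10 m reference, euphotic depth Z_eu from surface
  chlorophyll (log–log cubic), and depth-integrated biomass
  ∫₀^max(MLD, Z_eu) Chl dz.
* **Bloom phenology** — annual cycles from 1 July, ≥ 8 profiles in the
  November–February bloom window, 20-day bins, bloom magnitude = max bin
  mean of integrated chlorophyll; bloom typing
  (island/plateau > ice > ridge > HNLC) and a Kruskal–Wallis comparison of
  type magnitudes.
* **Eddy kinetic energy** — deep EKE from Argo parking-depth displacements
  (1°×1° boxes, > 5 samples, EKE = ½(u′² + v′²) from population variances,
  count-weighted Gaussian smoothing with a 100 km radius) and surface EKE
  from gridded velocity time series.
* **Density climatology & alongstream isopycnal diagnosis** — σ₀ at 25 dbar
  levels (0–2000 dbar) from QC'd hydrographic profiles, isotropic Gaussian
  optimal interpolation (550 km scale) onto a 0.5° grid, meridional sections
  at 28°E and 38°E, and the alongstream contrast Δσ(P, dh) in dynamic-height
  coordinate, relabelled to pseudo-latitude — so a meridional meander of the
  ACC front cancels and a genuine isopycnal shoaling survives.
* **Lagrangian iron delivery** — backward RK4 advection (6 h step, linear
  space–time velocity interpolation) from every seed point to its most
  recent contact with an iron source (shallow bathymetry < 500 m, or the
  upwelled-ridge disks at 30°E–50°S / 30.5°E–49.5°S, radius 1°); delivered
  iron fraction = exp(−age/τ) with scavenging e-folding time τ.
* **δ³He sections** — gridding of GLODAP-style helium-isotope stations into
  vertical sections, flagging stations in high-EKE (> 150 cm² s⁻²)
  environments.
* **Synthetic data** — every input kind can be generated with prescribed
  ground truth (bloom magnitude, EKE level, isopycnal tilt, plume shape),
  so each stage has a parameter-recovery test with no external data.

## Worked example

Generate a synthetic fixture set and run the bloom chain:

```sh
ventbloom simulate --seed 7 --out fixtures/
ventbloom blooms --profiles fixtures/profiles.csv --out out/
```

which prints (seed 7):

```
2 qualified bloom cycles -> out/blooms.csv
```

`out/blooms.csv` then contains one row per float-season, e.g.

```
float_id,season_start,magnitude_mg_m2,magnitude_date,lat,lon
SYN6901585,2014-07-01,81.0579,2014-11-08,-49.7011,31
SYN2902130,2015-07-01,93.8915,2015-11-08,-49.7011,34
```

The two floats were generated with prescribed bloom magnitudes of 83.0 and
96.5 mg Chl m⁻² (the two ridge-influenced blooms of the study region), with
40% daytime quenching and sensor noise; the chain recovers them to within
the 20-day binning tolerance (~2–3% low). Other subcommands: `eke`,
`climatology`, `advect`, `sections`, `report` (see `ventbloom --help`).

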