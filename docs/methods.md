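# Methods

## Scope and model structure

`peatenvelope` implements a presence/absence envelope model for peatland
distribution on a cell-centre registered geographic grid (default 10′).
The pipeline is: monthly climatology → annual equilibrium PET and
moisture index → per-cell predictor table (MI, MAT, slope, ALT,
elevation, MAP, PJJA) → threshold classification → evaluation against an
observed peat mask → optional future-scenario re-classification. All
stages are pure functions of their inputs; the only randomness in the
package lives in the synthetic-data generator, which is fully seeded.

## Radiation and equilibrium PET

PET is the equilibrium evapotranspiration

    Eeq = s/(s+γ) · Rn/λ,

evaluated at monthly mean temperature on each month's middle day
(365-day no-leap calendar) and scaled by the days in the month. This
matches monthly climatological inputs; against a daily-timestep
integration of the same formulation (drivers interpolated to every day),
the mid-month scheme agrees to well under 1% in annual totals.

Net radiation uses the STASH-family parameterisation:

- shortwave: `Rs = (c + d·Sf)(1 − α)·Ra` with transmissivity intercept
  c = 0.25, sunshine slope d = 0.5, albedo α = 0.17, and `Ra` the
  analytic daily top-of-atmosphere integral (solar constant
  1360 W m⁻², cosine declination approximation, sunset hour angle
  clamped for polar day/night);
- net longwave: `(b + (1 − b)·Sf)(A − T)` W m⁻² with b = 0.2,
  A = 107 W m⁻², integrated over the daylight hours;
- `Rn < 0` is floored at 0 for PET (no condensation credit).

Thermodynamic terms: Magnus saturation vapour-pressure slope,
λ = (2.501 − 0.002361·T)×10⁶ J kg⁻¹, and γ = cp·p/(0.622·λ) with
pressure from the ISA barometric formula at cell elevation
(`elevation_adjust_gamma`, default on — high-plateau cells sit above
3000 m where γ drops by a third). All constants live in one
`RadiationConstants` dataclass so alternates can be tested.

A note on magnitudes: for a wet-plateau reference cell (33.5°N, 3400 m,
MAT ≈ 1.4 °C, sunshine ≈ 0.42) this scheme yields an annual equilibrium
PET near 700 mm and hence MI ≈ 0.55 at MAP = 400 mm. Literature MI
values quoted for such cells (≈ 1.8–2.0) imply annual PET near 210 mm,
which no parameter choice within this radiation family reproduces at
that latitude — even zero sunshine gives ≈ 430 mm. The package reports
what the stated formulation computes; the constants remain configurable
for users who wish to explore alternative calibrations.

## Envelope rule

All defined bounds are inclusive (`strict_bounds` flips them to strict;
on continuous fields the difference is measure-zero). Missing values of
a constrained predictor pass the check by default (`missing_passes`):
the motivating case is ALT, which is undefined where there is no
permafrost, yet permafrost-free regions do host peatlands. The opposite
reading is one flag away.

Threshold derivation offers `minmax` and symmetric empirical `quantile`
(default q = 0.025; q = 0 degenerates to minmax; q ∈ [0, 0.5)). Minmax
bounds derived from a presence set always cover that set, so noise-free
reclassification is exact (kappa 1) — this is the package's main
self-consistency guarantee, exercised in the tests.

## Evaluation

Cohen's kappa uses marginal-product chance agreement
`Pe = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/N²`, `κ = (Po − Pe)/(1 − Pe)`.
Undefined metrics (no observed presences; Pe = 1) are reported as null
with a reason code, never coerced to 0. Cells missing in either mask
are excluded from the tallies and counted.

## Regridding and I/O

Bilinear regridding interpolates between source cell centres
(scipy `RegularGridInterpolator`); target centres outside the source
centre hull, or with any missing neighbour, come out missing. Target
centres that coincide with source centres take the source value
directly, making regridding onto the source grid the identity even next
to missing cells. Bilinear interpolation is exact for affine fields,
which the tests exploit as an analytic oracle.

Rasters and climatologies round-trip through CF-style NetCDF (xarray,
scipy backend) and long-format CSV. The CRU-style text reader accepts
the generic `lat lon v1…v12` dialect with a per-variable scale factor
(sunshine percent → fraction by default); the grid is inferred from the
distinct coordinates, and any inconsistent spacing is an error rather
than a guess.

## Future scenarios

Unit conversions: T(°C) = T(K) − 273.15; precipitation
mm/month = flux × 86 400 × days-in-month (no-leap calendar); sunshine
fraction = 1 − cloud fraction. The change signal is transferred by the
anomaly (delta) method: additive for temperature and sunshine (sunshine
clipped to [0, 1]), multiplicative for precipitation with the ratio
clamped to [0, 5] and defined as 1 where the GCM baseline month is
drier than 1 mm — guards against dry-cell blow-ups. `anomaly_mode="off"`
substitutes raw downscaled fields instead, for the no-bias-correction
reading. Ensemble means are cell-wise arithmetic means with
missing-aware counting.

## Synthetic data generator

The generator emulates the *statistical structure* the analysis
assumes, at order-of-magnitude fidelity, so that ground truth is known
exactly:

- **Terrain**: smoothed Gaussian random field (correlation length
  2.5 cells) around a 3500 m plateau base, amplitude 350 m; slope from
  the metric elevation gradient (longitude spacing shrinks with
  latitude).
- **Climate**: temperature and precipitation share a SE→NW aridity
  coordinate — wet-warm south-east (MAT 1 °C at base elevation,
  2000 mm/yr) to arid-cold north-west (−8 °C, 20 mm/yr, log-linear
  ramp) — plus an elevation lapse of 6.5 K/km, a ±9 °C seasonal cycle,
  summer-concentrated precipitation and winter-brighter sunshine
  (base 0.45). The MAP extremes are realised exactly at the corner
  cells. The default terrain is gentle (slopes < 2°), so the slope
  bound rarely binds in generated truths; the slope rule is exercised
  by direct fixtures in the tests.
- **Permafrost**: ALT decreases with elevation and is missing (no
  permafrost) wherever MAT exceeds 0.5 °C — which includes the wet SE
  corner, exercising the missing-ALT rule exactly where presences live.
- **Truth**: presence = envelope classification under configurable
  `true_thresholds` (default: the narrow preset), then i.i.d. Bernoulli
  flip noise ε ∈ [0, 0.5) per cell — the simplest misclassification
  model for an imperfect peat map; spatially correlated noise is out of
  scope. Coverage fractions are 1/0 or optionally smeared around the
  12.2% cutoff so the fractional-coverage machinery is exercised.

What passing tests do **not** show about real data: the generator has
no orographic precipitation, no interannual variability, no spatially
correlated mapping error, and its aridity gradient is far smoother than
real plateau climate; recovery results demonstrate correctness of the
machinery, not skill on real maps.

## Numerical choices and degenerate inputs

- Missing data are NaN everywhere; a cell missing any climate month is
  excluded from the environment table and from evaluation denominators,
  with the exclusion count logged.
- Cell membership is half-open (`[low, high)` both axes); a site on a
  shared edge belongs to the higher-index cell.
- Longitudes are used as given on a non-wrapping domain; antimeridian
  crossing is out of scope.
- The 12.2% coverage cutoff is inclusive (≥).
- Grid equality is tolerant to 1e−7 degrees so grids reconstructed from
  written coordinates compare equal.
- MI is undefined (NaN, counted) where annual PET ≤ 0; MAT is the
  unweighted mean of the 12 monthly means.

## Problem sizes

Tests and the acceptance script use a 40×40 cell domain for noise-free
recovery and 100×100 (10,000 cells) for flip-noise calibration; oracle
equivalences use 10,000 random cells × 50 threshold sets and 1,000
random confusion matrices. These sizes give binomial confidence
intervals tight enough to detect calibration errors of a fraction of a
percent while the whole suite stays in the tens of seconds.

## Known limitations

- The radiation scheme is the equilibrium family only — no
  Penman–Monteith, snow, or soil water balance.
- Evaluation offers the three published metrics; ROC/AUC or TSS are
  out of scope.
- Future ALT must be supplied as an input raster; the package never
  models permafrost dynamics.
- Only geographic lat/lon grids; polygon rasterisation is out of scope
  (fractional-coverage rasters are the accepted input).
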