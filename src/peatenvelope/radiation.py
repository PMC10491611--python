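"""Daily insolation, net radiation, equilibrium evapotranspiration and MI.

The moisture index MI = P/PET uses the radiation-driven *equilibrium*
evapotranspiration in place of a full PET formulation:

    Eeq = (s / (s + gamma)) * Rn / lambda

with s the slope of the saturation vapour-pressure curve at air
temperature, gamma the psychrometric constant, lambda the latent heat of
vaporisation and Rn the daily net radiation.  Net radiation follows the
STASH-family parameterisation: shortwave (c + d*Sf)(1 - albedo)*Ra with Sf
the fractional sunshine duration, and net longwave (b + (1 - b)*Sf)(A - T)
in W m-2 applied over the daylight hours.

All monthly quantities use a 365-day no-leap calendar with insolation
evaluated on each month's middle day, matching monthly climatological
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, MonthlyClimatology, RasterField

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: day-of-year of each month's middle day (no-leap calendar)
MID_MONTH_DAY = np.array([16, 45, 75, 105, 136, 166, 197, 228, 258, 289, 319, 350])

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class RadiationConstants:
    """Tunable constants of the net-radiation and PET scheme.

    All live here so alternates can be tested; defaults are the
    STASH-family values.
    """

    solar_constant: float = 1360.0   # W m-2
    albedo: float = 0.17             # shortwave surface albedo
    c: float = 0.25                  # transmissivity intercept
    d: float = 0.5                   # transmissivity sunshine slope
    b: float = 0.2                   # longwave cloud-correction intercept
    A: float = 107.0                 # W m-2, longwave temperature offset
    cp: float = 1013.0               # J kg-1 K-1, specific heat of moist air
    p0: float = 101_325.0            # Pa, sea-level pressure
    elevation_adjust_gamma: bool = True


DEFAULT_CONSTANTS = RadiationConstants()


def daily_insolation(latitude, day_of_year,
                     consts: RadiationConstants = DEFAULT_CONSTANTS):
    """Top-of-atmosphere insolation Ra (MJ m-2 d-1) and daylength (h).

    Standard astronomical formulae: solar declination from a cosine
    approximation, sunset hour angle clamped for polar day/night, and the
    analytic daily integral of the solar zenith cosine.
    Accepts scalars or arrays (broadcast together).
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    if np.any(np.abs(lat) > np.pi / 2 + 1e-12):
        raise ValueError("latitude must lie in [-90, 90]")
    day = np.asarray(day_of_year, dtype=float)
    decl = np.deg2rad(-23.44 * np.cos(2 * np.pi * (day + 10) / 365.0))
    u = np.sin(lat) * np.sin(decl)
    v = np.cos(lat) * np.cos(decl)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_hs = np.where(v > 0, -u / np.where(v > 0, v, 1.0), np.where(u > 0, -1.0, 1.0))
    cos_hs = np.clip(cos_hs, -1.0, 1.0)
    hs = np.arccos(cos_hs)  # sunset hour angle, radians
    daylength = 24.0 * hs / np.pi
    ra = (SECONDS_PER_DAY / np.pi) * consts.solar_constant * (
        u * hs + v * np.sin(hs)) / 1e6
    ra = np.maximum(ra, 0.0)
    return ra, daylength


def net_radiation(ra, sf, t_air, daylength,
                  consts: RadiationConstants = DEFAULT_CONSTANTS):
    """Daily net radiation Rn (MJ m-2 d-1), possibly negative.

    Shortwave: (c + d*Sf)(1 - albedo) * Ra.  Net longwave:
    (b + (1 - b)*Sf)(A - T) W m-2 integrated over the daylight hours.
    Callers treating Rn as an evaporative supply should floor it at zero.
    """
    sf = np.asarray(sf, dtype=float)
    flat = np.atleast_1d(sf)
    finite = flat[~np.isnan(flat)]
    if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
        raise ValueError("sunshine fraction must lie in [0, 1]")
    rs = (consts.c + consts.d * sf) * (1.0 - consts.albedo) * np.asarray(ra)
    rnl_w = (consts.b + (1.0 - consts.b) * sf) * (consts.A - np.asarray(t_air))
    rnl = rnl_w * np.asarray(daylength) * 3600.0 / 1e6
    return rs - rnl


def svp_slope(t_air):
    """Slope s (Pa K-1) of the Magnus saturation vapour-pressure curve."""
    t = np.asarray(t_air, dtype=float)
    es = 611.21 * np.exp(17.502 * t / (t + 240.97))
    return es * 17.502 * 240.97 / (t + 240.97) ** 2


def latent_heat(t_air):
    """Latent heat of vaporisation lambda (J kg-1) at air temperature."""
    return (2.501 - 0.002361 * np.asarray(t_air, dtype=float)) * 1e6


def air_pressure(elevation_m, consts: RadiationConstants = DEFAULT_CONSTANTS):
    """Barometric pressure (Pa) at elevation via the ISA lapse formula."""
    z = np.asarray(elevation_m, dtype=float)
    return consts.p0 * (1.0 - 0.0065 * z / 288.15) ** 5.25588


def psychrometric_constant(t_air, elevation_m=None,
                           consts: RadiationConstants = DEFAULT_CONSTANTS):
    """gamma = cp * p / (0.622 * lambda), in Pa K-1."""
    if elevation_m is not None and consts.elevation_adjust_gamma:
        p = air_pressure(elevation_m, consts)
    else:
        p = consts.p0
    return consts.cp * p / (0.622 * latent_heat(t_air))


def equilibrium_pet_day(latitude, day_of_year, t_air, sf, elevation_m=None,
                        consts: RadiationConstants = DEFAULT_CONSTANTS):
    """Equilibrium evapotranspiration for one day, in mm/day."""
    ra, dl = daily_insolation(latitude, day_of_year, consts)
    rn = np.maximum(net_radiation(ra, sf, t_air, dl, consts), 0.0)
    s = svp_slope(t_air)
    gamma = psychrometric_constant(t_air, elevation_m, consts)
    lam = latent_heat(t_air)
    # Rn in MJ -> J; kg m-2 of water == mm
    return (s / (s + gamma)) * rn * 1e6 / lam


@dataclass
class PETResult:
    """Monthly and annual equilibrium PET on the analysis grid (mm)."""

    grid: GridSpec
    pet_monthly: np.ndarray  # (12, n_lat, n_lon), mm/month
    pet_annual: np.ndarray   # (n_lat, n_lon), mm/yr


def equilibrium_pet(clim: MonthlyClimatology,
                    elevation: RasterField | None = None,
                    consts: RadiationConstants = DEFAULT_CONSTANTS) -> PETResult:
    """Annual equilibrium PET per cell from a monthly climatology.

    Each month is represented by its middle day: Eeq at the monthly mean
    temperature and sunshine on that day's insolation, scaled by the days
    in the month.  Cells missing temperature or sunshine in any month come
    out NaN.
    """
    grid = clim.grid
    lat2d = grid.lat_centers[:, None] * np.ones((1, grid.n_lon))
    elev = elevation.values if elevation is not None else None
    pet_m = np.empty((12, *grid.shape))
    for m in range(12):
        pet_m[m] = equilibrium_pet_day(
            lat2d, MID_MONTH_DAY[m], clim.tmp[m], clim.sun[m],
            elevation_m=elev, consts=consts) * DAYS_IN_MONTH[m]
    pet_m = np.maximum(pet_m, 0.0)
    # propagate missing months: equilibrium_pet_day already yields NaN there
    with np.errstate(invalid="ignore"):
        annual = pet_m.sum(axis=0)
    return PETResult(grid=grid, pet_monthly=pet_m, pet_annual=annual)


@dataclass
class MoistureIndexField:
    """MI = MAP/PET and MAP per cell; MI is NaN where PET <= 0 or missing."""

    grid: GridSpec
    mi: np.ndarray
    map_annual: np.ndarray
    n_undefined: int = 0


def moisture_index(map_annual, pet_annual):
    """MI = MAP / PET for scalars or arrays; NaN where PET <= 0."""
    map_a = np.asarray(map_annual, dtype=float)
    pet_a = np.asarray(pet_annual, dtype=float)
    if np.any(map_a[~np.isnan(map_a)] < 0):
        raise ValueError("annual precipitation must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.where(pet_a > 0, map_a / pet_a, np.nan)
    if mi.ndim == 0:
        return float(mi)
    return mi


def moisture_index_field(clim: MonthlyClimatology,
                         elevation: RasterField | None = None,
                         consts: RadiationConstants = DEFAULT_CONSTANTS
                         ) -> tuple[MoistureIndexField, PETResult]:
    """Compute MAP, annual PET and MI on the climatology's grid."""
    pet = equilibrium_pet(clim, elevation, consts)
    map_annual = clim.map_annual
    mi = moisture_index(map_annual, pet.pet_annual)
    n_undef = int(np.isnan(mi).sum() - (~clim.defined).sum())
    return (MoistureIndexField(grid=clim.grid, mi=mi, map_annual=map_annual,
                               n_undefined=max(n_undef, 0)),
            pet)
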