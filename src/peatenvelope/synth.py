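"""Synthetic plateau-like inputs with known ground truth.

The generator emulates the statistical structure of the real inputs at
order-of-magnitude fidelity: a 10' lat/lon domain with a smoothed random
elevation field around a high-plateau base, temperature driven by a lapse
rate plus a seasonal cycle, precipitation following a strong SE-to-NW
gradient (wet south-east, arid north-west), cloudier (less sunny) summers,
an active-layer-thickness field correlated with elevation and missing
where there is no permafrost, and a peat mask generated by classifying the
derived environment with *known* envelope thresholds and flipping each
cell independently with probability ``flip_noise``.

Because presence is generated from known thresholds, threshold-recovery
and metric calibration can be tested exactly: with no flip noise the mask
equals the envelope classification bit-for-bit, and with flip noise eps
the accuracy of the true-threshold classifier concentrates at 1 - eps.
All outputs are pure functions of the config (seeded determinism).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .envelope import (EnvelopeThresholds, NARROW, build_environment,
                       classify)
from .grids import (GridSpec, M_PER_DEG, MonthlyClimatology, PeatMask,
                    RasterField)
from .radiation import MoistureIndexField, RadiationConstants, \
    DEFAULT_CONSTANTS, moisture_index_field


@dataclass
class SynthConfig:
    """Parameters of the synthetic domain; identical configs give
    bit-identical outputs."""

    seed: int = 0
    n_lat: int = 40
    n_lon: int = 40
    lat0: float = 31.0          # deg, south edge
    lon0: float = 96.0          # deg, west edge
    resolution: float = 10.0    # arc-minutes

    # terrain
    elev_base: float = 3500.0       # m, plateau base elevation
    elev_amplitude: float = 350.0   # m, std of the smoothed random field
    correlation_length: float = 2.5  # cells, smoothing length

    # temperature: SE->NW cooling gradient plus elevation lapse
    mat_se: float = 1.0             # degC, MAT at the wet SE corner (base elev)
    mat_nw: float = -8.0            # degC, MAT at the arid NW corner
    lapse_rate: float = 6.5         # K/km
    seasonal_amplitude: float = 9.0  # degC, half-range of the annual cycle
    temp_noise: float = 0.2         # degC, smooth spatial noise per month

    # precipitation: log-linear SE->NW ramp of annual totals
    map_min: float = 20.0           # mm/yr at the arid NW corner
    map_max: float = 2000.0         # mm/yr at the wet SE corner
    precip_shape: float = 0.5       # <1 widens the wet SE sector
    precip_seasonality: float = 0.8  # summer concentration in [0, 1)

    # sunshine
    sun_base: float = 0.45
    sun_seasonal: float = 0.15      # winter-sunny / cloudy-monsoon-summer
    sun_noise: float = 0.03

    # permafrost / active layer
    alt_base: float = 1.6           # m at the base elevation
    alt_elev_coeff: float = -0.8    # m per km of elevation above base
    permafrost_mat_max: float = 0.5  # degC; warmer cells have no permafrost

    # ground truth
    true_thresholds: EnvelopeThresholds = field(default_factory=lambda: NARROW)
    flip_noise: float = 0.0
    fraction_smear: bool = False
    radiation: RadiationConstants = field(
        default_factory=lambda: DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        if self.n_lat < 8 or self.n_lon < 8:
            raise ValueError("domain must be at least 8x8 cells")
        if not 0.0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must lie in [0, 0.5)")
        if not 0.0 <= self.precip_seasonality < 1.0:
            raise ValueError("precip_seasonality must lie in [0, 1)")

    def grid(self) -> GridSpec:
        res = self.resolution / 60.0
        return GridSpec(lat_min=self.lat0,
                        lat_max=self.lat0 + self.n_lat * res,
                        lon_min=self.lon0,
                        lon_max=self.lon0 + self.n_lon * res,
                        resolution=self.resolution)


@dataclass
class SynthTruth:
    """A complete synthetic input bundle with its generating truth."""

    config: SynthConfig
    grid: GridSpec
    elevation: RasterField
    slope: RasterField
    alt: RasterField
    clim: MonthlyClimatology
    mi: MoistureIndexField
    env: pd.DataFrame
    envelope_presence: np.ndarray     # noise-free classification per env row
    peat: PeatMask                    # with flip noise applied
    true_thresholds: EnvelopeThresholds


@dataclass
class ScenarioFields:
    """A converted future scenario on the analysis grid."""

    label: str
    clim: MonthlyClimatology
    member: str = "synthetic"
    alt_future: RasterField | None = None


def _smooth_field(rng: np.random.Generator, shape, corr_len: float
                  ) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=corr_len, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def make_domain(cfg: SynthConfig
                ) -> tuple[GridSpec, RasterField, RasterField]:
    """Grid, elevation and slope.

    Elevation is a smoothed seeded random field around the plateau base;
    slope is the arctangent of the elevation gradient magnitude over the
    metric cell spacing (longitude spacing shrinks with latitude).
    """
    grid = cfg.grid()
    rng = np.random.default_rng(cfg.seed)
    elev = cfg.elev_base + cfg.elev_amplitude * _smooth_field(
        rng, grid.shape, cfg.correlation_length)
    slope = slope_from_elevation(grid, elev)
    return (grid,
            RasterField(grid=grid, values=elev, units="m", name="elevation"),
            RasterField(grid=grid, values=slope.values, units="deg",
                        name="slope"))


def slope_from_elevation(grid: GridSpec, elev: np.ndarray) -> RasterField:
    """Terrain slope (degrees) from an elevation field on the grid."""
    dy = grid.res_deg * M_PER_DEG
    dx = dy * np.cos(np.deg2rad(grid.lat_centers))[:, None]
    dz_dlat, dz_dlon = np.gradient(np.asarray(elev, dtype=float))
    gx = dz_dlon / dx
    gy = dz_dlat / dy
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return RasterField(grid=grid, values=slope, units="deg", name="slope")


def aridity_coordinate(cfg: SynthConfig, grid: GridSpec) -> np.ndarray:
    """Shared SE->NW gradient coordinate: 1 at the wet-warm SE corner,
    0 at the arid-cold NW corner, shaped by ``precip_shape``."""
    lat_c, lon_c = grid.lat_centers, grid.lon_centers
    lat_n = (lat_c - lat_c[0]) / (lat_c[-1] - lat_c[0])
    lon_n = (lon_c - lon_c[0]) / (lon_c[-1] - lon_c[0])
    se = ((1 - lat_n)[:, None] + lon_n[None, :]) / 2.0
    return se ** cfg.precip_shape


def make_climatology(cfg: SynthConfig, grid: GridSpec,
                     elevation: RasterField) -> MonthlyClimatology:
    """Monthly temperature, precipitation and sunshine on the domain.

    Both temperature and precipitation follow a shared SE-to-NW aridity
    coordinate (wet-warm south-east, arid-cold north-west), as on the real
    plateau.  tmp[m] = MAT(se) + seasonal cycle - lapse*(elev -
    elev_base)/1000 + smooth noise; annual precipitation ramps
    log-linearly from map_max at the SE corner to map_min at the NW corner
    and is split into months with a summer-peaked profile; sunshine is
    winter-bright and clipped to [0, 1].
    """
    rng = np.random.default_rng(cfg.seed + 1)
    elev = elevation.values
    months = np.arange(12)
    # annual cycle peaking in July (month index 6)
    cycle = np.cos(2 * np.pi * (months - 6) / 12.0)

    se_coord = aridity_coordinate(cfg, grid)
    mat_field = cfg.mat_nw + (cfg.mat_se - cfg.mat_nw) * se_coord

    tmp = np.empty((12, *grid.shape))
    for m in months:
        noise = cfg.temp_noise * _smooth_field(
            rng, grid.shape, cfg.correlation_length)
        tmp[m] = (mat_field + cfg.seasonal_amplitude * cycle[m]
                  - cfg.lapse_rate * (elev - cfg.elev_base) / 1000.0 + noise)

    log_map = (np.log(cfg.map_min)
               + (np.log(cfg.map_max) - np.log(cfg.map_min)) * se_coord)
    map_annual = np.exp(log_map)
    month_w = 1.0 + cfg.precip_seasonality * cycle
    month_w = month_w / month_w.sum()
    pre = month_w[:, None, None] * map_annual[None, :, :]

    sun = np.empty((12, *grid.shape))
    for m in months:
        noise = cfg.sun_noise * _smooth_field(
            rng, grid.shape, cfg.correlation_length)
        sun[m] = cfg.sun_base - cfg.sun_seasonal * cycle[m] + noise
    sun = np.clip(sun, 0.0, 1.0)

    return MonthlyClimatology(grid=grid, tmp=tmp, pre=pre, sun=sun)


def make_alt(cfg: SynthConfig, grid: GridSpec, elevation: RasterField,
             clim: MonthlyClimatology) -> RasterField:
    """Active layer thickness: smooth, elevation-correlated, and missing
    (no permafrost) where MAT exceeds ``permafrost_mat_max``."""
    rng = np.random.default_rng(cfg.seed + 2)
    alt = (cfg.alt_base
           + cfg.alt_elev_coeff * (elevation.values - cfg.elev_base) / 1000.0
           + 0.1 * _smooth_field(rng, grid.shape, cfg.correlation_length))
    alt = np.clip(alt, 0.1, None)
    alt = np.where(clim.mat > cfg.permafrost_mat_max, np.nan, alt)
    return RasterField(grid=grid, values=alt, units="m", name="ALT")


def make_truth(cfg: SynthConfig) -> SynthTruth:
    """Generate the full bundle: terrain, climate, environment, peat mask.

    Presence is the envelope classification under ``cfg.true_thresholds``,
    then flipped i.i.d. per cell with probability ``flip_noise``.  The
    coverage fraction is 1/0 (optionally smeared above/below the 12.2%
    cutoff) so the fractional-coverage machinery is exercised.
    """
    grid, elevation, slope = make_domain(cfg)
    clim = make_climatology(cfg, grid, elevation)
    alt = make_alt(cfg, grid, elevation, clim)
    mi, _pet = moisture_index_field(clim, elevation, cfg.radiation)
    env = build_environment(clim, mi, slope, alt, elevation)
    presence_rows = classify(env, cfg.true_thresholds)
    if not presence_rows.any():
        raise ValueError(
            "true thresholds select zero cells on this domain; widen the "
            "thresholds or change the climate parameters")

    presence = np.zeros(grid.shape, dtype=bool)
    presence[env["row"], env["col"]] = presence_rows

    rng = np.random.default_rng(cfg.seed + 3)
    noisy = presence.copy()
    if cfg.flip_noise > 0:
        flips = rng.random(grid.shape) < cfg.flip_noise
        noisy = presence ^ flips

    if cfg.fraction_smear:
        frac = np.where(noisy, rng.uniform(0.13, 1.0, grid.shape),
                        rng.uniform(0.0, 0.12, grid.shape))
    else:
        frac = noisy.astype(float)
    peat = PeatMask(grid=grid, presence=noisy, fraction=frac)

    return SynthTruth(config=cfg, grid=grid, elevation=elevation,
                      slope=slope, alt=alt, clim=clim, mi=mi, env=env,
                      envelope_presence=presence_rows, peat=peat,
                      true_thresholds=cfg.true_thresholds)


def make_future_scenario(cfg: SynthConfig, clim: MonthlyClimatology,
                         delta_t: float = 0.0, precip_factor: float = 1.0,
                         delta_sun: float = 0.0, label: str = "scenario",
                         t_ramp_per_cell: float = 0.0) -> ScenarioFields:
    """Perturb the baseline climatology into a future scenario.

    Uniform deltas by default; ``t_ramp_per_cell`` adds a south-to-north
    linear temperature ramp (degC per cell row) for displacement tests.
    """
    if precip_factor < 0:
        raise ValueError("precip_factor must be non-negative")
    grid = clim.grid
    ramp = t_ramp_per_cell * np.arange(grid.n_lat)[:, None]
    tmp = clim.tmp + delta_t + ramp[None, :, :]
    pre = clim.pre * precip_factor
    sun = np.clip(clim.sun + delta_sun, 0.0, 1.0)
    return ScenarioFields(
        label=label,
        clim=MonthlyClimatology(grid=grid, tmp=tmp, pre=pre, sun=sun))


def config_to_dict(cfg: SynthConfig) -> dict:
    """JSON/YAML-safe dump of a SynthConfig (for manifests)."""
    d = asdict(cfg)
    d["true_thresholds"] = cfg.true_thresholds.to_dict()
    return d
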