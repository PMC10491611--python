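"""Gridded data containers and regridding for the 10-arc-minute analysis grid.

Everything downstream (moisture index, envelope classification, evaluation,
projection) operates on a single cell-centre registered geographic lat/lon
grid, by default at 10' resolution.  This module defines the grid and the
raster/climatology/mask containers, reads CRU CL-style whitespace text
climatologies, regrids with bilinear interpolation, and turns fractional
peat-coverage rasters and point site lists into presence masks.

Missing data are represented as NaN throughout, never as silent zeros.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

logger = logging.getLogger(__name__)

#: metres per degree of latitude (mean Earth radius 6371 km)
M_PER_DEG = 111_194.9


class GridError(ValueError):
    """Raised for inconsistent or incompatible grid definitions."""


@dataclass(frozen=True, eq=False)
class GridSpec:
    """A cell-centre registered regular lat/lon grid.

    ``lat_min``/``lat_max``/``lon_min``/``lon_max`` are the *outer edges* of
    the domain in degrees; ``resolution`` is the cell size in arc-minutes
    (default 10').  Cell centres sit at ``edge + (i + 0.5) * resolution``.
    Cell membership is half-open: a point on a shared edge belongs to the
    higher-index cell.  Equality is tolerant to float round-off so grids
    reconstructed from written coordinates compare equal.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 10.0  # arc-minutes

    def __eq__(self, other) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return all(
            abs(getattr(self, f) - getattr(other, f)) < 1e-7
            for f in ("lat_min", "lat_max", "lon_min", "lon_max",
                      "resolution"))

    def __post_init__(self) -> None:
        res = self.res_deg
        for lo, hi, name in ((self.lat_min, self.lat_max, "lat"),
                             (self.lon_min, self.lon_max, "lon")):
            span = hi - lo
            if span <= 0:
                raise GridError(f"{name} extent is empty: [{lo}, {hi}]")
            n = span / res
            if abs(n - round(n)) > 1e-6:
                raise GridError(
                    f"{name} extent {span} deg is not an integer multiple of "
                    f"the {self.resolution}' resolution")

    @property
    def res_deg(self) -> float:
        return self.resolution / 60.0

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.res_deg))

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.res_deg))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.res_deg

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.res_deg

    def cell_of(self, lat: float, lon: float) -> tuple[int, int] | None:
        """Half-open cell lookup; ``None`` if the point is outside the grid."""
        i = int(np.floor((lat - self.lat_min) / self.res_deg))
        j = int(np.floor((lon - self.lon_min) / self.res_deg))
        if 0 <= i < self.n_lat and 0 <= j < self.n_lon:
            return i, j
        return None

    @classmethod
    def from_centers(cls, lats: np.ndarray, lons: np.ndarray,
                     resolution: float | None = None) -> "GridSpec":
        """Infer a grid from arrays of distinct cell-centre coordinates."""
        lats = np.unique(np.asarray(lats, dtype=float))
        lons = np.unique(np.asarray(lons, dtype=float))
        steps = []
        for arr, name in ((lats, "lat"), (lons, "lon")):
            if arr.size > 1:
                d = np.diff(arr)
                step = d.min()
                ratio = d / step
                if np.any(np.abs(ratio - np.round(ratio)) > 1e-4):
                    raise GridError(f"inconsistent {name} spacing: {d}")
                steps.append(step)
        if resolution is not None:
            res_deg = resolution / 60.0
        elif steps:
            res_deg = min(steps)
        else:
            raise GridError("cannot infer resolution from a single cell; "
                            "pass resolution explicitly")
        return cls(lat_min=float(lats[0] - res_deg / 2),
                   lat_max=float(lats[-1] + res_deg / 2),
                   lon_min=float(lons[0] - res_deg / 2),
                   lon_max=float(lons[-1] + res_deg / 2),
                   resolution=res_deg * 60.0)


@dataclass
class RasterField:
    """A 2-D field on a :class:`GridSpec`; NaN flags missing cells."""

    grid: GridSpec
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"field shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def copy_with(self, values: np.ndarray, **kw) -> "RasterField":
        out = replace(self, values=np.asarray(values, dtype=float))
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class MonthlyClimatology:
    """Twelve monthly layers of temperature, precipitation and sunshine.

    ``tmp`` is in deg C, ``pre`` in mm/month, ``sun`` is the fractional
    sunshine duration in [0, 1]; each has shape ``(12, n_lat, n_lon)``.
    """

    grid: GridSpec
    tmp: np.ndarray
    pre: np.ndarray
    sun: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tmp", "pre", "sun"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12, *self.grid.shape):
                raise GridError(f"{name} must have shape (12, n_lat, n_lon)")
            setattr(self, name, arr)
        if np.nanmin(self.pre, initial=0.0) < -1e-9:
            raise ValueError("precipitation must be non-negative")
        if (np.nanmin(self.sun, initial=0.0) < -1e-9
                or np.nanmax(self.sun, initial=0.0) > 1 + 1e-9):
            raise ValueError("sunshine fraction must lie in [0, 1]")

    @property
    def defined(self) -> np.ndarray:
        """Cells where all three variables have all twelve months."""
        return (~np.isnan(self.tmp).any(axis=0)
                & ~np.isnan(self.pre).any(axis=0)
                & ~np.isnan(self.sun).any(axis=0))

    @property
    def mat(self) -> np.ndarray:
        """Mean annual temperature, unweighted mean of the 12 monthly means."""
        return self.tmp.mean(axis=0)

    @property
    def map_annual(self) -> np.ndarray:
        """Mean annual precipitation (mm/yr)."""
        return self.pre.sum(axis=0)


#: fraction of a cell that must be peat-covered for the cell to count as peat
DEFAULT_PEAT_CUTOFF = 0.122


@dataclass
class PeatMask:
    """Boolean peat presence per cell, optionally backed by a fraction."""

    grid: GridSpec
    presence: np.ndarray
    fraction: np.ndarray | None = None
    cutoff: float = DEFAULT_PEAT_CUTOFF

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != self.grid.shape:
            raise GridError("presence shape does not match grid")

    @property
    def n_present(self) -> int:
        return int(self.presence.sum())


@dataclass
class SiteList:
    """Point records of peatland study sites."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"site_id", "lat", "lon"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        if self.table["site_id"].duplicated().any():
            raise ValueError("site_id values must be unique")
        lat, lon = self.table["lat"], self.table["lon"]
        if ((lat < -90) | (lat > 90)).any() or ((lon < -180) | (lon > 180)).any():
            raise ValueError("site coordinates outside valid lat/lon range")

    @classmethod
    def from_csv(cls, path) -> "SiteList":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# CRU CL-style text reader
# ---------------------------------------------------------------------------

#: per-variable (scale, units) applied to raw file values
CRU_VARIABLE_KINDS = {
    "tmp": (1.0, "degC"),
    "pre": (1.0, "mm/month"),
    "sunp": (0.01, "fraction"),  # file holds percent sunshine
}


def read_cru_text(path, variable_kind: str = "tmp",
                  scale: float | None = None) -> RasterField | None:
    """Read a CRU CL-style whitespace grid: ``lat lon v1 ... v12`` per line.

    Returns a 12-layer climatology packaged as a list of RasterFields is
    overkill; instead the twelve monthly values are returned stacked in a
    single array via the companion :func:`read_cru_monthly`.  This function
    is retained as the documented entry point and simply delegates.
    """
    return read_cru_monthly(path, variable_kind, scale)


def read_cru_monthly(path, variable_kind: str = "tmp",
                     scale: float | None = None):
    """Parse a CRU CL-style text file into ``(GridSpec, values[12, i, j])``.

    ``variable_kind`` selects the default scale factor and units from
    :data:`CRU_VARIABLE_KINDS`; an explicit ``scale`` overrides it.  The grid
    is inferred from the distinct lat/lon values in the file; cells absent
    from the file are NaN.
    """
    if variable_kind not in CRU_VARIABLE_KINDS:
        raise ValueError(f"unknown variable_kind {variable_kind!r}; "
                         f"expected one of {sorted(CRU_VARIABLE_KINDS)}")
    kind_scale, units = CRU_VARIABLE_KINDS[variable_kind]
    if scale is None:
        scale = kind_scale

    opener = gzip.open if str(path).endswith(".gz") else open
    lats, lons, rows = [], [], []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != 14:
                raise ValueError(
                    f"{path}:{lineno}: expected 14 numeric tokens "
                    f"(lat lon + 12 monthly values), got {len(tokens)}")
            try:
                nums = [float(t) for t in tokens]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric token") from exc
            lats.append(nums[0])
            lons.append(nums[1])
            rows.append(nums[2:])
    if not rows:
        raise ValueError(f"{path}: no records")

    grid = GridSpec.from_centers(np.array(lats), np.array(lons))
    values = np.full((12, grid.n_lat, grid.n_lon), np.nan)
    res = grid.res_deg
    for la, lo, vals in zip(lats, lons, rows):
        i = int(round((la - grid.lat_min) / res - 0.5))
        j = int(round((lo - grid.lon_min) / res - 0.5))
        ci, cj = grid.lat_centers[i], grid.lon_centers[j]
        if abs(ci - la) > 1e-4 or abs(cj - lo) > 1e-4:
            raise GridError(
                f"record at ({la}, {lo}) does not sit on the inferred grid")
        values[:, i, j] = np.array(vals) * scale
    return grid, values, units


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def regrid_bilinear(src: RasterField, target: GridSpec) -> RasterField:
    """Bilinearly interpolate ``src`` onto the cell centres of ``target``.

    Each target centre takes the bilinear interpolant of the four
    surrounding source centres; targets outside the source centre hull, or
    with any NaN neighbour, come out NaN.
    """
    if not np.any(src.defined):
        raise GridError("source field is entirely missing")
    sg = src.grid
    if (target.lat_min >= sg.lat_max or target.lat_max <= sg.lat_min
            or target.lon_min >= sg.lon_max or target.lon_max <= sg.lon_min):
        raise GridError("source and target grids do not overlap")

    interp = RegularGridInterpolator(
        (sg.lat_centers, sg.lon_centers), src.values,
        method="linear", bounds_error=False, fill_value=np.nan)
    tlat, tlon = np.meshgrid(target.lat_centers, target.lon_centers,
                             indexing="ij")
    points = np.column_stack([tlat.ravel(), tlon.ravel()])
    out = interp(points).reshape(target.shape)

    # target centres that coincide with source centres take the source
    # value directly, so regridding onto the source grid is the identity
    # even next to missing cells
    tol = 1e-6 * sg.res_deg
    si = np.searchsorted(sg.lat_centers, target.lat_centers)
    sj = np.searchsorted(sg.lon_centers, target.lon_centers)
    for arr, centers, src_centers in ((si, target.lat_centers,
                                       sg.lat_centers),
                                      (sj, target.lon_centers,
                                       sg.lon_centers)):
        np.clip(arr, 0, len(src_centers) - 1, out=arr)
        lower = np.maximum(arr - 1, 0)
        use_lower = (np.abs(src_centers[lower] - centers)
                     < np.abs(src_centers[arr] - centers))
        arr[use_lower] = lower[use_lower]
    hit_i = np.abs(sg.lat_centers[si] - target.lat_centers) < tol
    hit_j = np.abs(sg.lon_centers[sj] - target.lon_centers) < tol
    if hit_i.any() and hit_j.any():
        ti = np.nonzero(hit_i)[0]
        tj = np.nonzero(hit_j)[0]
        out[np.ix_(ti, tj)] = src.values[np.ix_(si[ti], sj[tj])]
    return RasterField(grid=target, values=out, units=src.units, name=src.name)


def regrid_climatology(clim: MonthlyClimatology,
                       target: GridSpec) -> MonthlyClimatology:
    """Bilinearly regrid all three monthly variables onto ``target``."""
    def do(stack, clip=None):
        out = np.empty((12, *target.shape))
        for m in range(12):
            f = RasterField(grid=clim.grid, values=stack[m])
            out[m] = regrid_bilinear(f, target).values
        if clip is not None:
            out = np.clip(out, *clip)
        return out

    return MonthlyClimatology(
        grid=target,
        tmp=do(clim.tmp),
        pre=do(clim.pre, clip=(0.0, np.inf)),
        sun=do(clim.sun, clip=(0.0, 1.0)),
    )


# ---------------------------------------------------------------------------
# Presence masks
# ---------------------------------------------------------------------------

def peat_mask_from_fraction(fraction: RasterField,
                            cutoff: float = DEFAULT_PEAT_CUTOFF) -> PeatMask:
    """Threshold a fractional peat-coverage raster into a presence mask.

    A cell is peat when its coverage fraction is at least ``cutoff``
    (inclusive); by default 12.2% coverage.
    """
    vals = fraction.values
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
        raise ValueError("coverage fraction must lie in [0, 1]")
    presence = np.where(np.isnan(vals), False, vals >= cutoff)
    mask = PeatMask(grid=fraction.grid, presence=presence,
                    fraction=vals, cutoff=cutoff)
    logger.info("peat mask: %d presence cells at cutoff %.3f",
                mask.n_present, cutoff)
    return mask


def sites_to_mask(sites: SiteList, grid: GridSpec) -> tuple[PeatMask, int]:
    """Bin point sites into grid cells; returns (mask, occupied-cell count).

    Membership follows the grid's half-open cell convention.  Sites falling
    outside the grid are excluded with a logged warning.
    """
    if len(sites) == 0:
        raise ValueError("site list is empty")
    presence = np.zeros(grid.shape, dtype=bool)
    n_excluded = 0
    for _, rec in sites.table.iterrows():
        cell = grid.cell_of(float(rec["lat"]), float(rec["lon"]))
        if cell is None:
            n_excluded += 1
            logger.warning("site %s at (%.4f, %.4f) outside grid; excluded",
                           rec["site_id"], rec["lat"], rec["lon"])
            continue
        presence[cell] = True
    if n_excluded:
        logger.warning("%d of %d sites fell outside the grid",
                       n_excluded, len(sites))
    mask = PeatMask(grid=grid, presence=presence, fraction=None, cutoff=0.0)
    return mask, mask.n_present
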