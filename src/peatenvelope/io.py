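"""NetCDF and CSV readers/writers for raster products.

Rasters round-trip through CF-style NetCDF (lat/lon coordinate variables,
written with xarray's scipy backend) and through long-format CSV tables
(lat, lon, value).  Missing cells stay NaN in both directions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec, MonthlyClimatology, PeatMask, RasterField

_ENGINE = "scipy"


def _grid_coords(grid: GridSpec) -> dict:
    return {"lat": ("lat", grid.lat_centers),
            "lon": ("lon", grid.lon_centers)}


def _grid_from_coords(ds: xr.Dataset) -> GridSpec:
    return GridSpec.from_centers(ds["lat"].values, ds["lon"].values)


def raster_to_netcdf(field: RasterField, path) -> None:
    name = field.name or "value"
    da = xr.DataArray(field.values, dims=("lat", "lon"),
                      coords=_grid_coords(field.grid), name=name,
                      attrs={"units": field.units})
    da.to_dataset().to_netcdf(path, engine=_ENGINE)


def raster_from_netcdf(path, var: str | None = None) -> RasterField:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        if var is None:
            var = next(iter(ds.data_vars))
        da = ds[var].load()
    return RasterField(grid=_grid_from_coords(ds), values=da.values,
                       units=da.attrs.get("units", ""), name=var)


def climatology_to_netcdf(clim: MonthlyClimatology, path) -> None:
    coords = {"month": ("month", np.arange(1, 13)), **_grid_coords(clim.grid)}
    ds = xr.Dataset(
        {"tmp": (("month", "lat", "lon"), clim.tmp, {"units": "degC"}),
         "pre": (("month", "lat", "lon"), clim.pre, {"units": "mm/month"}),
         "sun": (("month", "lat", "lon"), clim.sun, {"units": "1"})},
        coords=coords)
    ds.to_netcdf(path, engine=_ENGINE)


def climatology_from_netcdf(path) -> MonthlyClimatology:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    return MonthlyClimatology(grid=_grid_from_coords(ds),
                              tmp=ds["tmp"].values, pre=ds["pre"].values,
                              sun=ds["sun"].values)


def mask_to_netcdf(mask: PeatMask, path) -> None:
    data = {"presence": (("lat", "lon"), mask.presence.astype(np.int8))}
    if mask.fraction is not None:
        data["fraction"] = (("lat", "lon"), np.asarray(mask.fraction))
    ds = xr.Dataset(data, coords=_grid_coords(mask.grid),
                    attrs={"cutoff": mask.cutoff})
    ds.to_netcdf(path, engine=_ENGINE)


def mask_from_netcdf(path) -> PeatMask:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    frac = ds["fraction"].values if "fraction" in ds else None
    return PeatMask(grid=_grid_from_coords(ds),
                    presence=ds["presence"].values.astype(bool),
                    fraction=frac, cutoff=float(ds.attrs.get("cutoff", 0.0)))


def raster_to_csv(field: RasterField, path) -> None:
    grid = field.grid
    lat, lon = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")
    name = field.name or "value"
    pd.DataFrame({"lat": lat.ravel(), "lon": lon.ravel(),
                  name: field.values.ravel()}).to_csv(path, index=False)


def raster_from_csv(path, var: str | None = None) -> RasterField:
    df = pd.read_csv(path)
    if var is None:
        var = [c for c in df.columns if c not in ("lat", "lon")][0]
    grid = GridSpec.from_centers(df["lat"].values, df["lon"].values)
    values = np.full(grid.shape, np.nan)
    i = np.floor((df["lat"].values - grid.lat_min) / grid.res_deg).astype(int)
    j = np.floor((df["lon"].values - grid.lon_min) / grid.res_deg).astype(int)
    values[i, j] = df[var].values
    return RasterField(grid=grid, values=values, name=var)
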