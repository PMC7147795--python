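"""CF-style NetCDF reading/writing for gridded fields.

Datasets use dimensions (time, lat, lon) with ascending latitude, NaN
missing values carrying a ``_FillValue`` attribute, and a ``lon_convention``
attribute recording whether longitudes are in [0, 360) or [-180, 180).
Files are written with xarray's scipy backend (NetCDF3) so no binary
compression library is required.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import xarray as xr

from .fields import GeoGrid, ScalarField, VectorField

_FILL = np.nan

_VAR_UNITS = {
    "uwnd": "m s-1", "vwnd": "m s-1", "uo": "m s-1", "vo": "m s-1",
    "ssh": "m", "chl": "mg m-3", "sst": "degC", "precip": "mm day-1",
    "par": "einstein m-2 day-1",
}


def _lon_convention(lons: np.ndarray) -> str:
    return "[-180, 180)" if np.any(lons < 0) else "[0, 360)"


def fields_to_dataset(fields: Dict[str, ScalarField]) -> xr.Dataset:
    """Assemble named scalar fields sharing one grid into an xarray Dataset."""
    first = next(iter(fields.values()))
    grid = first.grid
    coords = {"lat": ("lat", grid.lats), "lon": ("lon", grid.lons)}
    data_vars = {}
    for name, fld in fields.items():
        if fld.grid.shape != grid.shape:
            raise ValueError("all fields must share one grid")
        dims: Tuple[str, ...] = ("lat", "lon")
        if fld.depths is not None:
            coords["depth"] = ("depth", fld.depths)
            dims = ("depth",) + dims
        if fld.times is not None:
            coords["time"] = ("time", fld.times)
            dims = ("time",) + dims
        attrs = {"units": fld.units or _VAR_UNITS.get(name, ""), "_FillValue": _FILL}
        data_vars[name] = (dims, fld.values, attrs)
    ds = xr.Dataset(data_vars, coords=coords)
    ds.lat.attrs.update(units="degrees_north", axis="Y")
    ds.lon.attrs.update(units="degrees_east", axis="X",
                        lon_convention=_lon_convention(grid.lons))
    ds.attrs["earth_radius_m"] = grid.earth_radius
    return ds


def write_fields(path, fields: Dict[str, ScalarField]) -> None:
    """Write named scalar fields to a NetCDF3 file."""
    fields_to_dataset(fields).to_netcdf(path, engine="scipy")


def write_vector_field(path, vec: VectorField, names=("uwnd", "vwnd")) -> None:
    u = ScalarField(vec.grid, vec.u, times=vec.times, depths=vec.depths,
                    units=vec.units)
    v = ScalarField(vec.grid, vec.v, times=vec.times, depths=vec.depths,
                    units=vec.units)
    write_fields(path, {names[0]: u, names[1]: v})


def grid_from_dataset(ds: xr.Dataset) -> GeoGrid:
    radius = float(ds.attrs.get("earth_radius_m", 6.371e6))
    return GeoGrid(ds["lat"].values, ds["lon"].values, earth_radius=radius)


def _axes_from_dataset(ds: xr.Dataset, da: xr.DataArray):
    times = ds["time"].values if "time" in da.dims else None
    depths = ds["depth"].values if "depth" in da.dims else None
    return times, depths


def read_scalar_field(path, var: str) -> ScalarField:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = grid_from_dataset(ds)
    da = ds[var]
    times, depths = _axes_from_dataset(ds, da)
    return ScalarField(grid, da.values, times=times, depths=depths, name=var,
                       units=str(da.attrs.get("units", "")))


def read_vector_field(path, uvar: str, vvar: str) -> VectorField:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = grid_from_dataset(ds)
    times, depths = _axes_from_dataset(ds, ds[uvar])
    return VectorField(grid, ds[uvar].values, ds[vvar].values, times=times,
                       depths=depths, units=str(ds[uvar].attrs.get("units", "")))
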