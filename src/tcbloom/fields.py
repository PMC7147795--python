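"""Gridded field containers shared by all diagnostics.

Fields live on a regular latitude/longitude grid.  Missing data are
represented as NaN; there is no separate mask array.  Array values always
carry latitude and longitude as the last two axes, with optional leading
time and/or depth axes, so differential operators can broadcast over any
leading dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

EARTH_RADIUS = 6.371e6
"""Mean Earth radius in metres used for all spherical geometry."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _check_axis(coord: np.ndarray, name: str) -> None:
    if coord.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if coord.size < 3:
        raise ValueError(f"{name} needs at least 3 points for centred differences")
    d = np.diff(coord)
    if not np.all(d > 0):
        raise ValueError(f"{name} must be strictly ascending")
    if np.max(np.abs(d - d[0])) > 1e-9:
        raise ValueError(f"{name} spacing must be uniform to within 1e-9 degrees")


@dataclass(frozen=True)
class GeoGrid:
    """Regular latitude/longitude grid.

    Parameters
    ----------
    lats : array of latitudes in degrees north, ascending, uniform spacing.
    lons : array of longitudes in degrees east, ascending, uniform spacing.
    earth_radius : sphere radius in metres.
    """

    lats: np.ndarray
    lons: np.ndarray
    earth_radius: float = EARTH_RADIUS

    def __post_init__(self):
        object.__setattr__(self, "lats", _as_float_array(self.lats))
        object.__setattr__(self, "lons", _as_float_array(self.lons))
        _check_axis(self.lats, "lats")
        _check_axis(self.lons, "lons")
        if np.any(np.abs(self.lats) > 90):
            raise ValueError("latitudes must lie in [-90, 90]")
        if self.earth_radius <= 0:
            raise ValueError("earth_radius must be positive")

    @property
    def shape(self) -> tuple:
        return (self.lats.size, self.lons.size)

    @property
    def dlat(self) -> float:
        """Latitude spacing in degrees."""
        return float(self.lats[1] - self.lats[0])

    @property
    def dlon(self) -> float:
        """Longitude spacing in degrees."""
        return float(self.lons[1] - self.lons[0])

    @property
    def lats_rad(self) -> np.ndarray:
        return np.deg2rad(self.lats)

    @property
    def lons_rad(self) -> np.ndarray:
        return np.deg2rad(self.lons)

    def meshgrid(self) -> tuple:
        """(lat2d, lon2d) in degrees, shape ``self.shape``."""
        return np.meshgrid(self.lats, self.lons, indexing="ij")


def _check_values(values: np.ndarray, grid: GeoGrid, name: str) -> np.ndarray:
    values = _as_float_array(values)
    if values.ndim < 2 or values.shape[-2:] != grid.shape:
        raise ValueError(
            f"{name} trailing axes {values.shape[-2:]} do not match grid {grid.shape}"
        )
    return values


@dataclass
class ScalarField:
    """Scalar values on a :class:`GeoGrid`, last two axes = (lat, lon)."""

    grid: GeoGrid
    values: np.ndarray
    times: Optional[np.ndarray] = None
    depths: Optional[np.ndarray] = None
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = _check_values(self.values, self.grid, "values")
        if self.times is not None:
            self.times = np.asarray(self.times)
        if self.depths is not None:
            self.depths = _as_float_array(self.depths)
            if np.any(np.diff(self.depths) <= 0):
                raise ValueError("depths must be strictly ascending")

    def with_values(self, values: np.ndarray, **meta) -> "ScalarField":
        kw = dict(times=self.times, depths=self.depths, name=self.name,
                  units=self.units)
        kw.update(meta)
        return ScalarField(self.grid, values, **kw)


@dataclass
class VectorField:
    """Horizontal vector components (eastward u, northward v) on a GeoGrid."""

    grid: GeoGrid
    u: np.ndarray
    v: np.ndarray
    times: Optional[np.ndarray] = None
    depths: Optional[np.ndarray] = None
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.u = _check_values(self.u, self.grid, "u")
        self.v = _check_values(self.v, self.grid, "v")
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have identical shapes")
        if self.times is not None:
            self.times = np.asarray(self.times)
        if self.depths is not None:
            self.depths = _as_float_array(self.depths)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)
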