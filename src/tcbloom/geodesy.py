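"""Spherical geometry helpers: great-circle distance and interpolation."""

from __future__ import annotations

import numpy as np

from .fields import EARTH_RADIUS


def haversine(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS):
    """Great-circle distance in metres between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def slerp(lat1, lon1, lat2, lon2, frac):
    """Great-circle interpolation between two points.

    ``frac`` in [0, 1]; 0 returns the first point, 1 the second.  Returns
    (lat, lon) in degrees.  Antipodal endpoints are rejected.
    """
    def unit(lat, lon):
        la, lo = np.deg2rad(lat), np.deg2rad(lon)
        return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo),
                         np.sin(la)])

    a, b = unit(lat1, lon1), unit(lat2, lon2)
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-12:
        p = a
    elif np.pi - omega < 1e-9:
        raise ValueError("cannot interpolate between antipodal points")
    else:
        p = (np.sin((1 - frac) * omega) * a + np.sin(frac * omega) * b) / np.sin(omega)
    lat = np.rad2deg(np.arcsin(np.clip(p[2], -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(p[1], p[0]))
    return float(lat), float(lon)


def local_tangent_offsets(lat, lon, lat0, lon0, radius: float = EARTH_RADIUS):
    """Eastward/northward displacement (m) of points from a reference point.

    Equirectangular approximation about the mid-latitude; adequate for
    vortex/eddy footprints of a few hundred km.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    midlat = np.deg2rad((lat + lat0) / 2.0)
    dx = radius * np.deg2rad(lon - lon0) * np.cos(midlat)
    dy = radius * np.deg2rad(lat - lat0)
    return dx, dy
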