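"""Finite differences on gridded fields.

Centred second-order differences at interior points, first-order one-sided
at the edges (``numpy.gradient`` with ``edge_order=1``).  Stencil policy for
missing data: NaNs poison every stencil they enter, and a NaN input cell
always yields a NaN output cell, even under the centred stencil that skips
the centre point.
"""

from __future__ import annotations

import numpy as np


def gradient_along(values: np.ndarray, coord: np.ndarray, axis: int) -> np.ndarray:
    """d(values)/d(coord) along ``axis`` with NaN poisoning of input cells."""
    out = np.gradient(values, coord, axis=axis, edge_order=1)
    out[np.isnan(values)] = np.nan
    return out


def dlon_derivative(values: np.ndarray, lons_rad: np.ndarray) -> np.ndarray:
    """Partial derivative with respect to longitude (radians), last axis."""
    return gradient_along(values, lons_rad, axis=-1)


def dlat_derivative(values: np.ndarray, lats_rad: np.ndarray) -> np.ndarray:
    """Partial derivative with respect to latitude (radians), second-to-last axis."""
    return gradient_along(values, lats_rad, axis=-2)
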