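"""Relative vorticity of current fields and box-averaged positive-vorticity
sections.

The planar definition curl_z = dv/dx - du/dy is implemented with the full
spherical metric,

    curl_z = 1/(R cos(phi)) dv/dlambda - 1/R du/dphi + u tan(phi)/R,

which reduces to the planar form locally; the tan(phi) metric term matters
little in the tropics but keeps the operator consistent with the spherical
wind-stress curl.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import BoxRegion, box_indexers
from .fields import GeoGrid, ScalarField, VectorField
from .numerics import dlat_derivative, dlon_derivative

VORTICITY_STATISTICS = ("pos_conditional_mean", "rectified_mean")


@dataclass
class VorticitySection:
    """Box-reduced positive-vorticity statistic per (time, depth)."""

    values: np.ndarray
    box: BoxRegion
    statistic: str
    times: np.ndarray | None = None
    depths: np.ndarray | None = None


def relative_vorticity(currents: VectorField, grid: GeoGrid | None = None) -> ScalarField:
    """curl_z of a current field in s^-1, spherical metric, per time/depth."""
    grid = grid or currents.grid
    lats_rad = grid.lats_rad
    if np.any(np.isclose(np.abs(lats_rad), np.pi / 2)):
        raise ValueError("grid touches a pole")
    cosphi = np.cos(lats_rad)[:, None]
    tanphi = np.tan(lats_rad)[:, None]
    R = grid.earth_radius
    dv_dlam = dlon_derivative(currents.v, grid.lons_rad)
    du_dphi = dlat_derivative(currents.u, lats_rad)
    curlz = dv_dlam / (R * cosphi) - du_dphi / R + currents.u * tanphi / R
    return ScalarField(grid, curlz, times=currents.times, depths=currents.depths,
                       name="relative_vorticity", units="s-1")


def positive_vorticity_box_mean(
    vort: ScalarField,
    box: BoxRegion,
    statistic: str = "pos_conditional_mean",
) -> VorticitySection:
    """Area-weighted positive-vorticity statistic inside a box.

    ``pos_conditional_mean``: cos(phi)-weighted mean over unmasked cells
    with curl_z > 0; 0 when no cell is positive.  ``rectified_mean``:
    weighted mean of max(curl_z, 0) over all unmasked cells.  Evaluated
    independently for every leading (time/depth) slice.
    """
    if statistic not in VORTICITY_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {VORTICITY_STATISTICS}"
        )
    ilat, ilon = box_indexers(vort.grid, box)
    sub = vort.values[..., ilat, :][..., :, ilon]
    w = np.cos(np.deg2rad(vort.grid.lats[ilat]))[:, None]
    w = np.broadcast_to(w, sub.shape[-2:])

    flat = sub.reshape(-1, sub.shape[-2] * sub.shape[-1])
    wflat = w.reshape(-1)
    out = np.zeros(flat.shape[0])
    for k, row in enumerate(flat):
        valid = ~np.isnan(row)
        if statistic == "pos_conditional_mean":
            sel = valid & (row > 0)
            out[k] = (
                np.sum(row[sel] * wflat[sel]) / np.sum(wflat[sel]) if sel.any() else 0.0
            )
        else:
            if not valid.any():
                out[k] = 0.0
            else:
                rect = np.maximum(row[valid], 0.0)
                out[k] = np.sum(rect * wflat[valid]) / np.sum(wflat[valid])
    out = out.reshape(sub.shape[:-2]) if sub.ndim > 2 else float(out[0])
    return VorticitySection(values=np.asarray(out), box=box, statistic=statistic,
                            times=vort.times, depths=vort.depths)
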