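"""Wind stress, wind-stress curl on the sphere, and Ekman pumping velocity.

The curl is evaluated exactly in the spherical form

    curl(tau) = 1/(R cos(phi)) * [ d(tau_y)/d(lambda) - d(tau_x cos(phi))/d(phi) ]

with the latitude derivative applied to the product tau_x*cos(phi), not
expanded.  Ekman pumping is w_E = curl(tau) / (rho_sw * f); rows within an
equator-mask latitude of the equator are masked because f -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import GeoGrid, ScalarField, VectorField
from .numerics import dlat_derivative, dlon_derivative

CD_SCHEMES = ("constant", "largepond")


@dataclass(frozen=True)
class EPVConstants:
    """Physical constants for the stress -> Ekman pumping chain."""

    rho_sw: float = 1024.0       # seawater density, kg m^-3
    omega: float = 7.2921e-5     # Earth rotation rate, s^-1
    rho_air: float = 1.2         # air density, kg m^-3
    cd_scheme: str = "constant"
    cd_constant: float = 1.3e-3

    def __post_init__(self):
        if self.rho_sw <= 0:
            raise ValueError("rho_sw must be positive")
        if self.cd_scheme not in CD_SCHEMES:
            raise ValueError(
                f"unknown cd_scheme {self.cd_scheme!r}; choose from {CD_SCHEMES}"
            )

    def coriolis(self, lat_deg) -> np.ndarray:
        """f = 2*Omega*sin(phi)."""
        return 2.0 * self.omega * np.sin(np.deg2rad(lat_deg))


def drag_coefficient(speed: np.ndarray, consts: EPVConstants) -> np.ndarray:
    """Dimensionless 10-m drag coefficient Cd(|U|).

    ``constant``: Cd = 1.3e-3 everywhere (keeps oracles analytic).
    ``largepond``: Large & Pond (1981) style piecewise rule,
    Cd = 1.2e-3 for |U| < 11 m/s, (0.49 + 0.065|U|)e-3 for 11-25 m/s,
    capped at its 25 m/s value in extreme winds.
    """
    speed = np.asarray(speed, dtype=float)
    if consts.cd_scheme == "constant":
        return np.full_like(speed, consts.cd_constant)
    capped = np.minimum(speed, 25.0)
    cd = np.where(capped < 11.0, 1.2e-3, (0.49 + 0.065 * capped) * 1e-3)
    return cd


def wind_stress(wind: VectorField, consts: EPVConstants = EPVConstants()) -> VectorField:
    """Bulk-formula surface stress (tau_x, tau_y) = rho_air*Cd(|U|)*|U|*(u, v)."""
    speed = wind.speed
    cd = drag_coefficient(speed, consts)
    factor = consts.rho_air * cd * speed
    return VectorField(
        wind.grid,
        factor * wind.u,
        factor * wind.v,
        times=wind.times,
        depths=wind.depths,
        name="wind_stress",
        units="N m-2",
    )


def wind_stress_curl(stress: VectorField, grid: GeoGrid | None = None) -> ScalarField:
    """Vertical curl of the wind stress on the sphere, in N m^-3."""
    grid = grid or stress.grid
    lats_rad = grid.lats_rad
    if np.any(np.isclose(np.abs(lats_rad), np.pi / 2)):
        raise ValueError("grid touches a pole; cos(phi) = 0 there")
    cosphi = np.cos(lats_rad)[:, None]
    dtauy_dlam = dlon_derivative(stress.v, grid.lons_rad)
    dtxcos_dphi = dlat_derivative(stress.u * cosphi, lats_rad)
    curl = (dtauy_dlam - dtxcos_dphi) / (grid.earth_radius * cosphi)
    return ScalarField(grid, curl, times=stress.times, depths=stress.depths,
                       name="wind_stress_curl", units="N m-3")


def ekman_pumping(
    curl: ScalarField,
    grid: GeoGrid | None = None,
    consts: EPVConstants = EPVConstants(),
    equator_mask_deg: float = 2.0,
) -> ScalarField:
    """Ekman pumping velocity w_E = curl(tau) / (rho_sw * f) in m/s.

    Positive values are upwelling in the Northern Hemisphere.  Rows with
    |latitude| < ``equator_mask_deg`` are NaN-masked (Coriolis singularity).
    """
    grid = grid or curl.grid
    f = consts.coriolis(grid.lats)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        we = curl.values / (consts.rho_sw * f)
    we = np.where(np.abs(grid.lats)[:, None] < equator_mask_deg, np.nan, we)
    return ScalarField(grid, we, times=curl.times, depths=curl.depths,
                       name="ekman_pumping_velocity", units="m s-1")
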