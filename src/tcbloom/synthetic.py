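"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the observational products the diagnostics consume: a
translating Rankine-type cyclone wind field, Gaussian cyclonic eddies in
sea surface height with geostrophic currents, tanh-thermocline hydrographic
profiles, a cloud-masked chlorophyll field whose bloom lags the cyclone
passage by a configurable number of days, and matching SST / PAR /
precipitation responses.  Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .fields import GeoGrid, ScalarField, VectorField
from .geodesy import haversine, local_tangent_offsets
from .profiles import HydroProfile
from .track import TCTrack
from .wind import EPVConstants

G = 9.81


# ---------------------------------------------------------------------------
# parameter types

@dataclass(frozen=True)
class VortexParams:
    """Rankine-type cyclone: solid-body core, power-law outer decay."""

    vmax: float                      # peak tangential wind, m/s
    rmax: float                      # radius of maximum wind, km
    decay_exponent: float = 0.5
    background_wind: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.vmax < 0:
            raise ValueError("vmax must be non-negative")
        if self.rmax <= 0:
            raise ValueError("rmax must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")


@dataclass(frozen=True)
class EddySpec:
    """Gaussian SSH anomaly; negative amplitude = cyclonic (NH)."""

    center: Tuple[float, float]      # (lat degN, lon degE)
    amplitude: float                 # m
    radius: float                    # e-folding radius, km

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class StratificationParams:
    """tanh thermocline between surface and abyssal T/S values."""

    sst: float
    deep_t: float
    thermocline_depth: float         # m, positive down
    thermocline_width: float         # m
    sss: float = 35.0
    deep_s: float = 35.0

    def __post_init__(self):
        if self.thermocline_depth <= 0 or self.thermocline_width <= 0:
            raise ValueError("thermocline depth and width must be positive")
        if self.sst <= self.deep_t:
            raise ValueError("sst must exceed deep_t")


@dataclass(frozen=True)
class BloomScenario:
    """Lagged chlorophyll response with i.i.d. Bernoulli cloud masking."""

    baseline_chl: float
    peak_chl: float
    lag_days: int
    cloud_fraction: float = 0.0
    seed: int = 0
    relax_efold_days: float = 3.0

    def __post_init__(self):
        if not 0.0 <= self.cloud_fraction < 1.0:
            raise ValueError("cloud_fraction must lie in [0, 1)")
        if self.peak_chl < self.baseline_chl:
            raise ValueError("peak_chl must be >= baseline_chl")
        if self.lag_days < 0:
            raise ValueError("lag_days must be non-negative")


# ---------------------------------------------------------------------------
# cyclone wind field

def rankine_speed(r_km, params: VortexParams) -> np.ndarray:
    """Tangential speed at radius r (km): linear core, power-law skirt."""
    r = np.asarray(r_km, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        outer = params.vmax * (params.rmax / r) ** params.decay_exponent
    return np.where(r <= params.rmax, params.vmax * r / params.rmax, outer)


def gen_vortex_wind(
    track: TCTrack,
    params: VortexParams,
    grid: GeoGrid,
    times: Sequence,
) -> VectorField:
    """Counterclockwise (NH cyclonic) vortex winds about the moving centre.

    The centre is interpolated along the track at each requested time;
    times outside the track span raise ``ValueError``.
    """
    times = pd.DatetimeIndex(times)
    lat2d, lon2d = grid.meshgrid()
    u = np.zeros((len(times),) + grid.shape)
    v = np.zeros_like(u)
    bgu, bgv = params.background_wind
    for k, t in enumerate(times):
        clat, clon = track.interpolate_position(t)
        dx, dy = local_tangent_offsets(lat2d, lon2d, clat, clon,
                                       radius=grid.earth_radius)
        r = np.hypot(dx, dy)
        vt = rankine_speed(r / 1000.0, params)
        with np.errstate(divide="ignore", invalid="ignore"):
            uhat = np.where(r > 0, -dy / r, 0.0)
            vhat = np.where(r > 0, dx / r, 0.0)
        u[k] = vt * uhat + bgu
        v[k] = vt * vhat + bgv
    return VectorField(grid, u, v, times=times.values, name="wind", units="m s-1")


# ---------------------------------------------------------------------------
# eddies: SSH + geostrophic currents

def gen_eddy_ssh_currents(
    eddies: Sequence[EddySpec],
    grid: GeoGrid,
    consts: EPVConstants = EPVConstants(),
) -> Tuple[ScalarField, VectorField]:
    """Superposed Gaussian SSH anomalies and their geostrophic currents.

    u = -(g/f) d(eta)/dy, v = (g/f) d(eta)/dx; a negative-amplitude eddy is
    cyclonic (counterclockwise, positive vorticity) in the NH.  Grids that
    reach within 2 degrees of the equator are rejected (f -> 0).
    """
    if np.any(np.abs(grid.lats) < 2.0):
        raise ValueError("geostrophy undefined within 2 degrees of the equator")
    lat2d, lon2d = grid.meshgrid()
    ssh = np.zeros(grid.shape)
    for e in eddies:
        d = haversine(lat2d, lon2d, e.center[0], e.center[1],
                      radius=grid.earth_radius)
        ssh += e.amplitude * np.exp(-(d / 1000.0) ** 2 / (2.0 * e.radius**2))

    from .numerics import dlat_derivative, dlon_derivative

    cosphi = np.cos(grid.lats_rad)[:, None]
    deta_dx = dlon_derivative(ssh, grid.lons_rad) / (grid.earth_radius * cosphi)
    deta_dy = dlat_derivative(ssh, grid.lats_rad) / grid.earth_radius
    f = consts.coriolis(grid.lats)[:, None]
    u = -(G / f) * deta_dy
    v = (G / f) * deta_dx
    return (
        ScalarField(grid, ssh, name="ssh", units="m"),
        VectorField(grid, u, v, name="geostrophic_current", units="m s-1"),
    )


# ---------------------------------------------------------------------------
# hydrography

def gen_profile(params: StratificationParams, depths: Sequence[float]) -> HydroProfile:
    """tanh-thermocline T/S profile on the given depth levels.

    The tanh transition is rescaled so the surface value equals ``sst``
    (``sss``) exactly; the buoyancy-frequency maximum sits at
    ``thermocline_depth``.
    """
    z = np.asarray(depths, dtype=float)
    if np.any(np.diff(z) <= 0):
        raise ValueError("depths must be strictly increasing")

    def ramp(surface, deep):
        g = 0.5 * (1.0 - np.tanh((z - params.thermocline_depth)
                                 / params.thermocline_width))
        g0 = 0.5 * (1.0 + np.tanh(params.thermocline_depth
                                  / params.thermocline_width))
        return deep + (surface - deep) * g / g0

    return HydroProfile(
        depth=z,
        temp=ramp(params.sst, params.deep_t),
        sal=ramp(params.sss, params.deep_s),
    )


# ---------------------------------------------------------------------------
# cyclone-relative timing

def closest_approach_times(
    track: TCTrack, grid: GeoGrid, times: Sequence
) -> np.ndarray:
    """Per-pixel time (index into ``times``) of closest cyclone approach.

    The centre is interpolated at each sample time, so the returned times
    are members of ``times`` (ties resolve to the earliest).  Sample times
    outside the track span are excluded from the search; when no sample
    falls within the span, positions clamped to the nearest endpoint are
    used instead.  Returns an integer array of shape ``grid.shape``.
    """
    times = pd.DatetimeIndex(times)
    t0, t1 = track.times[0], track.times[-1]
    in_span = (times >= t0) & (times <= t1)
    lat2d, lon2d = grid.meshgrid()
    dist = np.full((len(times),) + grid.shape, np.inf)
    for k, t in enumerate(times):
        if not in_span[k] and in_span.any():
            continue
        tc = min(max(t, t0), t1)
        clat, clon = track.interpolate_position(tc)
        dist[k] = haversine(lat2d, lon2d, clat, clon, radius=grid.earth_radius)
    return np.argmin(dist, axis=0)


def closest_approach_time_to_point(
    track: TCTrack, lat: float, lon: float, times: Sequence
) -> pd.Timestamp:
    """Sample time (from ``times``) when the cyclone centre is nearest a point."""
    times = pd.DatetimeIndex(times)
    t0, t1 = track.times[0], track.times[-1]
    in_span = (times >= t0) & (times <= t1)
    dists = np.full(len(times), np.inf)
    for k, t in enumerate(times):
        if not in_span[k] and in_span.any():
            continue
        tc = min(max(t, t0), t1)
        clat, clon = track.interpolate_position(tc)
        dists[k] = haversine(lat, lon, clat, clon)
    return times[int(np.argmin(dists))]


def make_linear_track(
    start: Tuple[float, float],
    end: Tuple[float, float],
    start_time,
    duration_hours: float = 48.0,
    msw: float = 35.0,
    fix_interval_hours: float = 6.0,
) -> TCTrack:
    """Straight constant-speed track between two (lat, lon) points."""
    from .track import TCFix

    n = int(round(duration_hours / fix_interval_hours)) + 1
    t0 = pd.Timestamp(start_time)
    fixes = []
    for i in range(n):
        frac = i / (n - 1)
        lat = start[0] + frac * (end[0] - start[0])
        lon = start[1] + frac * (end[1] - start[1])
        fixes.append(
            TCFix(time=t0 + pd.Timedelta(hours=i * fix_interval_hours),
                  lat=lat, lon=lon, msw=msw)
        )
    return TCTrack(fixes)


def _days_since(times: pd.DatetimeIndex, ca_idx: np.ndarray) -> np.ndarray:
    """(ntime, nlat, nlon) array of days since each pixel's closest approach."""
    day = (times.values - times.values[0]) / np.timedelta64(1, "D")
    ca_day = day[ca_idx]
    return day[:, None, None] - ca_day[None, :, :]


# ---------------------------------------------------------------------------
# biological / surface responses

def gen_bloom_fields(
    track: TCTrack,
    scenario: BloomScenario,
    grid: GeoGrid,
    times: Sequence,
) -> ScalarField:
    """Cloud-masked chlorophyll with a lagged post-passage bloom.

    Each pixel rises linearly from baseline to peak over ``lag_days`` days
    after its closest cyclone approach, then relaxes exponentially
    (e-folding ``relax_efold_days``).  Pixels are masked i.i.d. per
    pixel-day with probability ``cloud_fraction``; identical seeds give
    bit-identical output.
    """
    times = pd.DatetimeIndex(times)
    ca_idx = closest_approach_times(track, grid, times)
    d = _days_since(times, ca_idx)

    amp = scenario.peak_chl - scenario.baseline_chl
    lag = float(scenario.lag_days)
    if lag > 0:
        rise = np.clip(d / lag, 0.0, 1.0)
    else:
        rise = (d >= 0).astype(float)
    relax = np.exp(-np.clip(d - lag, 0.0, None) / scenario.relax_efold_days)
    shape = np.where(d < 0, 0.0, np.minimum(rise, relax))
    chl = scenario.baseline_chl + amp * shape

    rng = np.random.default_rng(scenario.seed)
    clouds = rng.random(chl.shape) < scenario.cloud_fraction
    chl = np.where(clouds, np.nan, chl)
    return ScalarField(grid, chl, times=times.values, name="chl", units="mg m-3")


def gen_sst_field(
    track: TCTrack,
    grid: GeoGrid,
    times: Sequence,
    base_sst: float = 29.0,
    drop: float = 2.0,
    duration_days: float = 10.0,
) -> ScalarField:
    """SST with a step cooling of ``drop`` degC for ``duration_days`` after
    each pixel's cyclone passage, then instant recovery."""
    times = pd.DatetimeIndex(times)
    ca_idx = closest_approach_times(track, grid, times)
    d = _days_since(times, ca_idx)
    cold = (d > 0) & (d <= duration_days)
    sst = np.where(cold, base_sst - drop, base_sst)
    return ScalarField(grid, sst, times=times.values, name="sst", units="degC")


def gen_par_field(
    track: TCTrack,
    grid: GeoGrid,
    times: Sequence,
    base_par: float = 45.0,
    dip: float = 25.0,
    width_days: float = 2.0,
) -> ScalarField:
    """PAR with a Gaussian dip centred on local cyclone passage."""
    times = pd.DatetimeIndex(times)
    ca_idx = closest_approach_times(track, grid, times)
    d = _days_since(times, ca_idx)
    par = base_par - dip * np.exp(-((d / width_days) ** 2))
    return ScalarField(grid, par, times=times.values, name="par",
                       units="einstein m-2 day-1")


def gen_precip_field(
    track: TCTrack,
    grid: GeoGrid,
    times: Sequence,
    peak_precip: float = 100.0,
    width_days: float = 1.5,
) -> ScalarField:
    """Precipitation pulse centred on local cyclone passage, mm/day."""
    times = pd.DatetimeIndex(times)
    ca_idx = closest_approach_times(track, grid, times)
    d = _days_since(times, ca_idx)
    pr = peak_precip * np.exp(-((d / width_days) ** 2))
    return ScalarField(grid, pr, times=times.values, name="precip",
                       units="mm day-1")
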