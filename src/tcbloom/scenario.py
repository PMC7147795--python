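"""End-to-end synthetic scenarios: generate, analyze, compare to ground truth.

A scenario builds every synthetic input (cyclone track and winds, eddy SSH
and currents, stratified profile, lagged cloud-masked chlorophyll, cooled
SST), runs the full diagnostic chain over a study box, and reports both the
recovered quantities and the generator's ground truth.  This is the engine
behind the ``report`` CLI and the end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .boxes import BoxRegion, bloom_metrics, box_mean, cooling_metrics
from .fields import GeoGrid
from .profiles import stratification_summary
from .synthetic import (
    BloomScenario,
    EddySpec,
    StratificationParams,
    VortexParams,
    closest_approach_time_to_point,
    gen_bloom_fields,
    gen_eddy_ssh_currents,
    gen_profile,
    gen_sst_field,
    gen_vortex_wind,
    make_linear_track,
)
from .track import TCTrack
from .vorticity import positive_vorticity_box_mean, relative_vorticity
from .wind import EPVConstants, ekman_pumping, wind_stress, wind_stress_curl


@dataclass
class ScenarioConfig:
    """Flat configuration mirroring the generator parameter types."""

    # grid
    lat_min: float = 9.0
    lat_max: float = 16.0
    lon_min: float = 65.0
    lon_max: float = 72.0
    spacing: float = 0.25
    # record
    start_date: str = "2017-11-22"
    n_days: int = 29
    # track: straight line through the box centre
    track_start: Tuple[float, float] = (8.0, 72.0)
    track_end: Tuple[float, float] = (17.0, 65.0)
    track_start_time: str = "2017-12-01 00:00"
    track_duration_hours: float = 36.0
    track_msw: float = 35.0
    # vortex winds
    vmax: float = 35.0
    rmax: float = 50.0
    decay_exponent: float = 0.5
    background_u: float = 0.0
    background_v: float = 0.0
    # eddy
    eddy_amplitude: float = -0.1
    eddy_radius: float = 100.0
    # stratification
    sst: float = 29.0
    deep_t: float = 12.0
    thermocline_depth: float = 46.2
    thermocline_width: float = 10.0
    sss: float = 36.5
    deep_s: float = 35.0
    depth_max: float = 200.0
    depth_step: float = 1.0
    # bloom
    baseline_chl: float = 0.26
    peak_chl: float = 3.2
    lag_days: int = 4
    cloud_fraction: float = 0.3
    relax_efold_days: float = 3.0
    # sst response
    sst_drop: float = 2.0
    sst_drop_days: float = 10.0
    # study box
    box_lat_min: float = 11.0
    box_lat_max: float = 14.0
    box_lon_min: float = 67.0
    box_lon_max: float = 70.0
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("track_start", "track_end"):
            if key in known:
                known[key] = tuple(float(x) for x in str(known[key]).split(","))
        return cls(**known)

    def to_file(self, path) -> None:
        data = asdict(self)
        data["track_start"] = ",".join(str(x) for x in self.track_start)
        data["track_end"] = ",".join(str(x) for x in self.track_end)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    # -- derived pieces ----------------------------------------------------
    def grid(self) -> GeoGrid:
        lats = np.arange(self.lat_min, self.lat_max + self.spacing / 2, self.spacing)
        lons = np.arange(self.lon_min, self.lon_max + self.spacing / 2, self.spacing)
        return GeoGrid(lats, lons)

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def track(self) -> TCTrack:
        return make_linear_track(
            self.track_start,
            self.track_end,
            self.track_start_time,
            duration_hours=self.track_duration_hours,
            msw=self.track_msw,
        )

    def box(self) -> BoxRegion:
        return BoxRegion(self.box_lat_min, self.box_lat_max,
                         self.box_lon_min, self.box_lon_max)

    def vortex(self) -> VortexParams:
        return VortexParams(self.vmax, self.rmax, self.decay_exponent,
                            (self.background_u, self.background_v))

    def stratification(self) -> StratificationParams:
        return StratificationParams(self.sst, self.deep_t, self.thermocline_depth,
                                    self.thermocline_width, self.sss, self.deep_s)

    def bloom(self) -> BloomScenario:
        return BloomScenario(self.baseline_chl, self.peak_chl, self.lag_days,
                             self.cloud_fraction, self.seed, self.relax_efold_days)

    def eddy(self) -> EddySpec:
        center = ((self.box_lat_min + self.box_lat_max) / 2,
                  (self.box_lon_min + self.box_lon_max) / 2)
        return EddySpec(center=center, amplitude=self.eddy_amplitude,
                        radius=self.eddy_radius)


def run_scenario(cfg: ScenarioConfig, seed: Optional[int] = None) -> dict:
    """Generate the full synthetic scenario and run every diagnostic on it.

    Returns a flat dict of recovered metrics alongside the injected ground
    truth, suitable for tabulation.
    """
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    grid = cfg.grid()
    times = cfg.times()
    track = cfg.track()
    box = cfg.box()
    box_center = ((cfg.box_lat_min + cfg.box_lat_max) / 2,
                  (cfg.box_lon_min + cfg.box_lon_max) / 2)

    passage = closest_approach_time_to_point(track, *box_center, times)
    baseline_end = _first_box_entry(track, box, times) or passage

    # chlorophyll bloom
    chl = gen_bloom_fields(track, cfg.bloom(), grid, times)
    chl_series = box_mean(chl, box)
    bloom = bloom_metrics(chl_series, passage, baseline_window_days=6.0,
                          baseline_end=baseline_end)

    # SST cooling
    sst = gen_sst_field(track, grid, times, base_sst=cfg.sst, drop=cfg.sst_drop,
                        duration_days=cfg.sst_drop_days)
    sst_series = box_mean(sst, box)
    max_drop, persistence = cooling_metrics(
        sst_series, passage, baseline_window_days=6.0, baseline_end=baseline_end
    )

    # eddy vorticity
    ssh, currents = gen_eddy_ssh_currents([cfg.eddy()], grid)
    vort = relative_vorticity(currents)
    ilat = int(np.argmin(np.abs(grid.lats - box_center[0])))
    ilon = int(np.argmin(np.abs(grid.lons - box_center[1])))
    center_vort = float(vort.values[ilat, ilon])
    pos_vort = positive_vorticity_box_mean(vort, box)

    # stratification
    depths = np.arange(0.0, cfg.depth_max + cfg.depth_step / 2, cfg.depth_step)
    profile = gen_profile(cfg.stratification(), depths)
    summary = stratification_summary(profile)

    # winds -> Ekman pumping at the passage time
    wind = gen_vortex_wind(track, cfg.vortex(), grid, [passage])
    stress = wind_stress(wind)
    curl = wind_stress_curl(stress)
    epv = ekman_pumping(curl)
    clat, clon = track.interpolate_position(passage)
    jlat = int(np.argmin(np.abs(grid.lats - clat)))
    jlon = int(np.argmin(np.abs(grid.lons - clon)))
    epv_core = float(epv.values[0, jlat, jlon])
    epv_min = float(np.nanmin(epv.values))

    return {
        "passage_time": str(passage),
        "true_lag_days": cfg.lag_days,
        "recovered_lag_days": bloom.lag_days,
        "true_fold_increase": cfg.peak_chl / cfg.baseline_chl,
        "recovered_fold_increase": bloom.fold_increase,
        "recovered_peak_chl": bloom.peak_value,
        "recovered_baseline_chl": bloom.baseline,
        "true_sst_drop": cfg.sst_drop,
        "recovered_sst_drop": max_drop,
        "true_cooling_days": cfg.sst_drop_days,
        "recovered_cooling_days": persistence,
        "true_thermocline_depth": cfg.thermocline_depth,
        "recovered_thermocline_depth": summary.thermocline_depth,
        "recovered_n_max": summary.n_max,
        "recovered_mld": summary.mld,
        "eddy_center_vorticity": center_vort,
        "box_positive_vorticity": float(np.asarray(pos_vort.values)),
        "epv_core": epv_core,
        "epv_ring_min": epv_min,
    }


def _first_box_entry(track: TCTrack, box: BoxRegion, times) -> Optional[pd.Timestamp]:
    """First sample time at which the (in-span) cyclone centre lies in the box."""
    times = pd.DatetimeIndex(times)
    t0, t1 = track.times[0], track.times[-1]
    for t in times:
        if t < t0 or t > t1:
            continue
        lat, lon = track.interpolate_position(t)
        if (box.lat_min <= lat <= box.lat_max) and (box.lon_min <= lon <= box.lon_max):
            return t
    return None
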