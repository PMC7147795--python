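"""Best-track ingestion, translation speed and intensity classification.

A track is an ordered list of 6-hourly fixes (time, lat, lon, maximum
sustained wind).  Translation speed at fix *i* is the great-circle distance
from fix *i-1* divided by the elapsed time, reported at the arrival fix so
the first fix carries no speed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .fields import EARTH_RADIUS
from .geodesy import haversine, slerp

#: Intensity categories ordered by increasing wind speed.  The published
#: band edges leave (41, 42) and (51, 52) unassigned; each gap is closed
#: upward so the classifier is total: [10.8, 17.2), [17.2, 24.5),
#: [24.5, 32.7), [32.7, 42), [42, 52), [52, inf).
INTENSITY_CATEGORIES = (
    "below_depression",
    "tropical_depression",
    "tropical_storm",
    "severe_tropical_storm",
    "typhoon",
    "severe_typhoon",
    "super_severe_typhoon",
)

_BAND_EDGES = np.array([10.8, 17.2, 24.5, 32.7, 42.0, 52.0])


@dataclass(frozen=True)
class TCFix:
    """A single best-track fix."""

    time: pd.Timestamp
    lat: float
    lon: float
    msw: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if self.msw < 0:
            raise ValueError("maximum sustained wind must be non-negative")


class TCTrack:
    """Time-ordered sequence of :class:`TCFix` with derived kinematics."""

    def __init__(self, fixes: Sequence[TCFix]):
        if len(fixes) < 2:
            raise ValueError("a track needs at least 2 fixes")
        times = pd.DatetimeIndex([f.time for f in fixes])
        if (times[1:] <= times[:-1]).any():
            raise ValueError("fix times must be strictly increasing")
        self.fixes: List[TCFix] = list(fixes)

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([f.time for f in self.fixes])

    @property
    def lats(self) -> np.ndarray:
        return np.array([f.lat for f in self.fixes])

    @property
    def lons(self) -> np.ndarray:
        return np.array([f.lon for f in self.fixes])

    @property
    def msw(self) -> np.ndarray:
        return np.array([f.msw for f in self.fixes])

    def interpolate_position(self, when) -> tuple:
        """Great-circle position of the centre at an arbitrary time.

        Raises ``ValueError`` for times outside the track span.
        """
        when = pd.Timestamp(when)
        times = self.times
        if when < times[0] or when > times[-1]:
            raise ValueError(
                f"time {when} outside track span [{times[0]}, {times[-1]}]"
            )
        i = int(np.searchsorted(times.values, np.datetime64(when), side="right")) - 1
        i = min(i, len(self) - 2)
        a, b = self.fixes[i], self.fixes[i + 1]
        frac = (when - a.time) / (b.time - a.time)
        return slerp(a.lat, a.lon, b.lat, b.lon, float(frac))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.times,
                "lat": self.lats,
                "lon": self.lons,
                "msw": self.msw,
            }
        )
        ts = translation_speed(self)
        df["ts"] = ts
        df["category"] = [classify_intensity(w) for w in self.msw]
        return df

    def write_csv(self, path, time_format: str = "%m/%d/%H") -> None:
        with open(path, "w") as fh:
            fh.write("lat,lon,time,msw\n")
            for f in self.fixes:
                fh.write(
                    f"{f.lat},{f.lon},{f.time.strftime(time_format)},{f.msw}\n"
                )


def parse_track(source: Union[str, "io.TextIOBase"], year: int) -> TCTrack:
    """Parse a track CSV with columns lat, lon, time (MM/DD/HH), msw.

    ``source`` may be a file path or the CSV text itself.  The year is not
    stored in the table and must be supplied; month rollover (e.g. November
    to December) is handled by monotonicity within one year.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()

    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if lines and any(c.isalpha() for c in lines[0]):
        lines = lines[1:]  # header row
    if len(lines) < 2:
        raise ValueError("track needs at least 2 data rows")

    fixes = []
    seen_times = set()
    for lineno, ln in enumerate(lines, start=1):
        parts = [p for p in ln.replace(",", " ").split() if p]
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 fields, got {len(parts)}")
        try:
            lat, lon = float(parts[0]), float(parts[1])
            mm, dd, hh = (int(x) for x in parts[2].split("/"))
            msw = float(parts[3])
            time = pd.Timestamp(year=year, month=mm, day=dd, hour=hh)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {lineno}: malformed row {ln!r}") from exc
        if time in seen_times:
            raise ValueError(f"line {lineno}: duplicate timestamp {time}")
        seen_times.add(time)
        fixes.append(TCFix(time=time, lat=lat, lon=lon, msw=msw))
    return TCTrack(fixes)


def translation_speed(track: TCTrack, radius: float = EARTH_RADIUS) -> np.ndarray:
    """Per-fix translation speed in m/s; NaN at the first fix.

    Speed at fix i is the haversine distance from fix i-1 divided by the
    elapsed seconds (6371-km sphere).
    """
    lats, lons, times = track.lats, track.lons, track.times
    out = np.full(len(track), np.nan)
    for i in range(1, len(track)):
        dt = (times[i] - times[i - 1]).total_seconds()
        if dt <= 0:
            raise ValueError("zero or negative elapsed time between fixes")
        d = haversine(lats[i - 1], lons[i - 1], lats[i], lons[i], radius=radius)
        out[i] = d / dt
    return out


def classify_intensity(msw: float) -> str:
    """Map maximum sustained wind (m/s) to an intensity category.

    Half-open bands per :data:`INTENSITY_CATEGORIES`; total on [0, inf).
    """
    if msw < 0 or not np.isfinite(msw):
        raise ValueError(f"msw must be finite and non-negative, got {msw}")
    idx = int(np.searchsorted(_BAND_EDGES, msw, side="right"))
    return INTENSITY_CATEGORIES[idx]
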