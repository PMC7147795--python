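"""Stratification diagnostics from temperature/salinity profiles.

Density comes from a linear equation of state by default (every test stays
analytic); TEOS-10 is delegated to ``gsw`` when installed.  The buoyancy
frequency N is evaluated at layer midpoints from first differences of
density; statically unstable layers are reported as N = 0 with a flag so
the argmax used for thermocline detection stays well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

G = 9.81
RHO0 = 1024.0
# linear equation-of-state coefficients
EOS_ALPHA = 2.0e-4   # thermal expansion, 1/degC
EOS_BETA = 7.6e-4    # haline contraction, 1/psu
EOS_T0 = 20.0
EOS_S0 = 35.0


@dataclass
class HydroProfile:
    """Depth-ordered temperature/salinity profile; depth positive down, metres."""

    depth: np.ndarray
    temp: np.ndarray
    sal: np.ndarray
    station: Optional[dict] = None

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        self.sal = np.asarray(self.sal, dtype=float)
        n = self.depth.size
        if n < 3 or self.temp.size != n or self.sal.size != n:
            raise ValueError("profile needs >= 3 levels of equal length")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depths must be strictly increasing (positive down)")


@dataclass
class NProfile:
    """Buoyancy frequency at layer midpoints, with instability flags."""

    depth: np.ndarray     # midpoint depths, m
    n: np.ndarray         # buoyancy frequency, s^-1 (0 where unstable)
    unstable: np.ndarray  # True where N^2 < 0 was clipped


@dataclass
class StratificationSummary:
    n_profile: NProfile
    thermocline_depth: Optional[float]
    n_max: float
    mld: Optional[float]
    flags: list = field(default_factory=list)


def density(profile: HydroProfile, eos: str = "linear") -> np.ndarray:
    """In-situ density per level, kg m^-3.

    ``linear``: rho = rho0 * (1 - alpha*(T - T0) + beta*(S - S0)).
    ``teos10``: gsw_rho at the profile's pressure (requires gsw).
    """
    if eos == "linear":
        return RHO0 * (
            1.0 - EOS_ALPHA * (profile.temp - EOS_T0) + EOS_BETA * (profile.sal - EOS_S0)
        )
    if eos == "teos10":
        try:
            import gsw
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("eos='teos10' requires the gsw package") from exc
        lat = (profile.station or {}).get("lat", 0.0)
        lon = (profile.station or {}).get("lon", 0.0)
        p = gsw.p_from_z(-profile.depth, lat)
        sa = gsw.SA_from_SP(profile.sal, p, lon, lat)
        ct = gsw.CT_from_t(sa, profile.temp, p)
        return gsw.rho(sa, ct, p)
    raise ValueError(f"unknown eos {eos!r}; choose 'linear' or 'teos10'")


def buoyancy_frequency(
    profile: HydroProfile, eos: str = "linear", smooth: bool = False
) -> NProfile:
    """N(z) at layer midpoints: N^2 = (g/rho0) * drho/dz, z positive down.

    Stable stratification (density increasing downward) gives N > 0.
    Negative N^2 is clipped to 0 and flagged.  ``smooth`` applies a 3-point
    running mean to N^2 (useful for real float data, off by default).
    """
    rho = density(profile, eos=eos)
    dz = np.diff(profile.depth)
    n2 = (G / RHO0) * np.diff(rho) / dz
    if smooth and n2.size >= 3:
        kernel = np.ones(3) / 3.0
        inner = np.convolve(n2, kernel, mode="valid")
        n2 = np.concatenate([[n2[0]], inner, [n2[-1]]])
    unstable = n2 < 0
    n = np.sqrt(np.clip(n2, 0.0, None))
    mid = 0.5 * (profile.depth[:-1] + profile.depth[1:])
    return NProfile(depth=mid, n=n, unstable=unstable)


def thermocline_depth(n_profile: NProfile) -> Optional[float]:
    """Midpoint depth of maximum N; ties go to the shallowest; None if N == 0."""
    if n_profile.n.size == 0:
        raise ValueError("empty buoyancy-frequency profile")
    if np.all(n_profile.n == 0):
        return None  # unstratified
    return float(n_profile.depth[int(np.argmax(n_profile.n))])


def mixed_layer_depth(
    profile: HydroProfile, dT: float = 0.2, zref: float = 10.0
) -> Optional[float]:
    """Shallowest depth where T < T(zref) - dT, linearly interpolated.

    None when the criterion is never met within the profile ("deeper than
    profile").
    """
    if profile.depth[-1] < zref:
        raise ValueError("profile does not reach the reference depth")
    t_ref = float(np.interp(zref, profile.depth, profile.temp))
    threshold = t_ref - dT
    below = profile.depth >= zref
    z = profile.depth[below]
    t = profile.temp[below]
    hits = np.where(t < threshold)[0]
    if hits.size == 0:
        return None
    i = hits[0]
    if i == 0:
        return float(z[0])
    z0, z1, t0, t1 = z[i - 1], z[i], t[i - 1], t[i]
    return float(z0 + (t0 - threshold) / (t0 - t1) * (z1 - z0))


def stratification_summary(
    profile: HydroProfile,
    eos: str = "linear",
    dT: float = 0.2,
    zref: float = 10.0,
    smooth: bool = False,
) -> StratificationSummary:
    """Full diagnostic bundle: N(z), thermocline depth, max N, mixed layer depth."""
    npro = buoyancy_frequency(profile, eos=eos, smooth=smooth)
    flags = []
    if npro.unstable.any():
        flags.append("unstable_layers")
    tdepth = thermocline_depth(npro)
    if tdepth is None:
        flags.append("unstratified")
    try:
        mld = mixed_layer_depth(profile, dT=dT, zref=zref)
    except ValueError:
        mld = None
        flags.append("profile_too_shallow_for_mld")
    if mld is None and "profile_too_shallow_for_mld" not in flags:
        flags.append("mld_deeper_than_profile")
    return StratificationSummary(
        n_profile=npro,
        thermocline_depth=tdepth,
        n_max=float(np.max(npro.n)),
        mld=mld,
        flags=flags,
    )


def read_profile_text(path) -> HydroProfile:
    """Read a 3-column (depth_m, temp_C, sal_psu) whitespace/comma text file."""
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#") or any(c.isalpha() for c in ln.split()[0]):
                continue
            parts = ln.replace(",", " ").split()
            rows.append([float(x) for x in parts[:3]])
    arr = np.asarray(rows)
    return HydroProfile(depth=arr[:, 0], temp=arr[:, 1], sal=arr[:, 2])


def write_profile_text(profile: HydroProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# depth_m temp_C sal_psu\n")
        for z, t, s in zip(profile.depth, profile.temp, profile.sal):
            fh.write(f"{z:.3f} {t:.6f} {s:.6f}\n")
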