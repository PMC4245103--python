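"""Sensor calibration and the integrated light-attenuation index LA250.

The tag log-compresses blue-light intensity (W cm^-2) to a three-digit
level at 20 levels per decade, anchored so that 1e-5 W cm^-2 reads level
150 (manufacturer check levels: 1e-5, 1e-7, 1e-9 W cm^-2 -> 150, 110, 70).
LA250 = (LL_0 - LL_250) / 250 m, in level units per metre; through the
log-linear calibration it is proportional to the mean diffuse attenuation
coefficient over the top 250 m, LA250 = (20 / ln 10) * K, and is invariant
to surface irradiance.  Only dives starting within an hour of local noon
(1100-1300 local solar time) contribute to the daily index, and a seal-day
is analysable only with 3 or more such light profiles.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dives import DiveCycle
from .hydrography import FrontalZone
from .io import Deployment

NOON_WINDOW_H = (11.0, 13.0)
MIN_PROFILES_PER_DAY = 3
LA250_DEPTH_M = 250.0
SENSOR_FLOOR_LEVEL = 25.0  # deep levels below this are at the sensor floor


@dataclass(frozen=True)
class CalibrationCurve:
    """Log-linear level/intensity map of the on-board light compression."""

    reference_intensity: float = 1e-5   # W cm^-2
    reference_level: float = 150.0
    levels_per_decade: float = 20.0
    level_min: float = 0.0
    level_max: float = 250.0


DEFAULT_CALIBRATION = CalibrationCurve()


def level_from_intensity(intensity, cal: CalibrationCurve = DEFAULT_CALIBRATION,
                         quantize: bool = False):
    """Light level for an intensity in W cm^-2 (scalar or array).

    level = reference_level + levels_per_decade * log10(I / I_ref), clamped
    to the valid level range; ``quantize`` rounds to the nearest integer
    level as the logger does.  Raises on non-positive intensity.
    """
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("intensity must be positive")
    level = cal.reference_level + cal.levels_per_decade * np.log10(
        arr / cal.reference_intensity)
    level = np.clip(level, cal.level_min, cal.level_max)
    if quantize:
        level = np.rint(level)
    return float(level) if np.isscalar(intensity) else level


def intensity_from_level(level, cal: CalibrationCurve = DEFAULT_CALIBRATION):
    """Inverse of the (unclamped) calibration map; raises out of range."""
    arr = np.asarray(level, dtype=float)
    if np.any((arr < cal.level_min) | (arr > cal.level_max)):
        raise ValueError(
            f"level outside valid range [{cal.level_min}, {cal.level_max}]")
    intensity = cal.reference_intensity * 10.0 ** (
        (arr - cal.reference_level) / cal.levels_per_decade)
    return float(intensity) if np.isscalar(level) else intensity


def surface_light_ll0(depth: np.ndarray, light: np.ndarray,
                      wet: np.ndarray) -> float | None:
    """LL_0: mean light level of wet, sub-surface (0 < depth <= 10 m) records
    at the end of the ascent phase; dry (above-surface) records are excluded.
    ``None`` when no record qualifies."""
    depth = np.asarray(depth, dtype=float)
    mask = (depth > 0.0) & (depth <= 10.0) & np.asarray(wet, dtype=bool)
    if not mask.any():
        return None
    return float(np.mean(np.asarray(light, dtype=float)[mask]))


def light_at_250(depth: np.ndarray, light: np.ndarray,
                 target_depth: float = LA250_DEPTH_M) -> float | None:
    """Light level linearly interpolated at 250 m along one phase; ``None``
    when the phase does not bracket the target depth."""
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0 or depth.min() > target_depth or depth.max() < target_depth:
        return None
    order = np.argsort(depth, kind="stable")
    return float(np.interp(target_depth, depth[order],
                           np.asarray(light, dtype=float)[order]))


def la250(deployment: Deployment, dive: DiveCycle,
          depth: np.ndarray | None = None,
          floor_level: float = SENSOR_FLOOR_LEVEL,
          z: float = LA250_DEPTH_M) -> float | None:
    """LA250 of one dive: (LL_0 - LL_250) / z in levels per metre.

    LL_250 averages the descent and ascent interpolations when both exist
    (mirroring the phase-averaging used for light inflections), otherwise
    uses the one available.  Dives whose LL_250 sits below the sensor floor
    (default level 25; the sensor resolves dawn/dusk only to ~300 m in clear
    water) contribute nothing, as do dives with no valid LL_0.
    """
    d = deployment.depth if depth is None else depth
    light = deployment.light_level
    asc = dive.ascent
    ll0 = surface_light_ll0(d[asc], light[asc], deployment.wet[asc])
    if ll0 is None:
        return None
    phases = []
    for sl in (dive.descent, dive.ascent_underwater):
        val = light_at_250(d[sl], light[sl], z)
        if val is not None:
            phases.append(val)
    if not phases:
        return None
    ll250 = float(np.mean(phases))
    if ll250 < floor_level:
        return None
    return (ll0 - ll250) / z


def local_solar_time(time_utc, lon: float):
    """Local solar time in decimal hours: UTC hours + lon/15, wrapped to
    [0, 24).  ``time_utc`` may be a timestamp or an array of timestamps."""
    t = np.asarray(time_utc)
    if np.issubdtype(t.dtype, np.datetime64):
        secs = t.astype("datetime64[s]").astype("int64") % 86400
        hours = secs / 3600.0
        out = (hours + lon / 15.0) % 24.0
        return float(out) if t.ndim == 0 else out
    ts = pd.to_datetime(time_utc)
    if isinstance(ts, (pd.DatetimeIndex, pd.Series)):
        hours = np.asarray(ts.hour + ts.minute / 60.0 + ts.second / 3600.0,
                           dtype=float)
    else:
        hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    return (hours + lon / 15.0) % 24.0


def noon_filter(dives: list[DiveCycle], lon: float,
                window: tuple[float, float] = NOON_WINDOW_H) -> list[DiveCycle]:
    """Dives whose start time falls within an hour of local noon
    (local solar time in [11.0, 13.0]).  Idempotent."""
    lo, hi = window
    timed = [d for d in dives if d.start_time is not None]
    if not timed:
        return []
    lst = local_solar_time(
        np.asarray([d.start_time for d in timed], dtype="datetime64[ns]"), lon)
    return [d for d, t in zip(timed, lst) if lo <= t <= hi]


@dataclass
class NoonIndexEstimate:
    """Per seal-day noon index: LA250 averaged over qualifying dives, with
    the matching T200/frontal-zone context at the day's noon position."""

    seal_id: str
    date: dt.date
    lat: float
    lon: float
    la250: float
    n_profiles: int
    t200: float | None = None
    zone: FrontalZone | None = None

    @property
    def analysable(self) -> bool:
        return self.n_profiles >= MIN_PROFILES_PER_DAY


def daily_noon_la250(la_values, seal_id: str, date: dt.date,
                     lat: float, lon: float,
                     t200_value: float | None = None,
                     zone: FrontalZone | None = None) -> NoonIndexEstimate | None:
    """Aggregate one seal-day's per-dive LA250 values into a noon estimate;
    ``None`` when no dive qualified.  Estimates with fewer than 3 profiles
    are produced but flagged non-analysable."""
    vals = [v for v in la_values if v is not None and np.isfinite(v)]
    if not vals:
        return None
    return NoonIndexEstimate(
        seal_id=seal_id, date=date, lat=lat, lon=lon,
        la250=float(np.mean(vals)), n_profiles=len(vals),
        t200=t200_value, zone=zone,
    )
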