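"""Geodesic distance, stepping-range speed and positional-outlier screening.

Distances use the Haversine great-circle formula on a sphere (mean
Earth radius 6 371 000 m by default).  GPS speed is derived over a
*stepping range* — the interval in retained fixes between the
positions used for each distance estimate — which suppresses the
additive coordinate-precision error that dominates fix-to-fix
distances at 1 Hz.  Extreme outliers are found by comparing the
interpolation-completed track (RF) against its rolling-median
counterpart (MeFF): seconds whose RF-to-MeFF distance exceeds the
threshold Z fail the protocol outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track_io import GpsFixSeries

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class SpeedSeries:
    """Stepping-range GPS speed per grid second.

    ``valid`` is False wherever the second is not covered by an
    interval between retained fixes.
    """

    time: np.ndarray
    speed_raw: np.ndarray
    speed_s: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class JitterSeries:
    """Per-second RF-to-MeFF distance and the Z-threshold decision."""

    time: np.ndarray
    jitter_dist: np.ndarray
    outlier: np.ndarray

    def __len__(self) -> int:
        return len(self.time)


def haversine(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance in metres between coordinate pairs.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    args = [np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2)]
    if any(np.any(~np.isfinite(a)) for a in args):
        raise ValueError("non-finite coordinate")
    p1, l1, p2, l2 = (np.radians(a) for a in args)
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * radius * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return d if d.ndim else float(d)


def _haversine_allow_nan(lat1, lon1, lat2, lon2, radius):
    """Vectorised Haversine that propagates NaN instead of raising."""
    p1, l1, p2, l2 = (np.radians(np.asarray(a, dtype=float))
                      for a in (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def derive_speed(fixes: GpsFixSeries, stepping_range: int = 5,
                 smooth_window: int = 5,
                 radius: float = EARTH_RADIUS_M) -> SpeedSeries:
    """GPS speed from distances between every ``stepping_range``-th fix.

    Missing fixes are not included: retained fixes are every
    ``stepping_range``-th *non-missing* fix starting from the first.
    The Haversine distance between consecutive retained fixes, divided
    by the elapsed seconds, is assigned to every second of that
    interval; a centre-aligned rolling mean of ``smooth_window``
    seconds is then applied on the 1 Hz grid.  Seconds outside any
    interval are flagged invalid.
    """
    if stepping_range < 1:
        raise ValueError("stepping_range must be >= 1")
    n = len(fixes)
    speed_raw = np.full(n, np.nan)
    nm = np.flatnonzero(~fixes.missing)
    retained = nm[::stepping_range]
    if len(retained) >= 2:
        i, j = retained[:-1], retained[1:]
        dist = _haversine_allow_nan(fixes.lat[i], fixes.lon[i],
                                    fixes.lat[j], fixes.lon[j], radius)
        dt = (fixes.time[j] - fixes.time[i]).astype(float)
        seg_speed = dist / dt
        for a, b, s in zip(i, j, seg_speed):
            speed_raw[a:b] = s
    valid = np.isfinite(speed_raw)
    roll = pd.Series(speed_raw).rolling(smooth_window, center=True, min_periods=1)
    speed_s = roll.mean().to_numpy()
    speed_s[~valid] = np.nan
    return SpeedSeries(fixes.time.copy(), speed_raw, speed_s, valid)


def interpolate_missing(fixes: GpsFixSeries) -> GpsFixSeries:
    """Fill missing slots by linear interpolation in lat/lon vs time (RF).

    Leading/trailing missing slots copy the nearest real fix.  Filled
    slots are flagged ``interpolated``.
    """
    if np.all(fixes.missing):
        raise ValueError("cannot interpolate an all-missing series")
    lat = pd.Series(fixes.lat, index=fixes.time)
    lon = pd.Series(fixes.lon, index=fixes.time)
    lat = lat.interpolate(method="index", limit_direction="both")
    lon = lon.interpolate(method="index", limit_direction="both")
    interp = fixes.interpolated | fixes.missing
    return GpsFixSeries(fixes.time.copy(), lat.to_numpy(), lon.to_numpy(),
                        np.zeros(len(fixes), dtype=bool), interp,
                        dop=fixes.dop, n_sats=fixes.n_sats)


def median_filter_track(rf: GpsFixSeries, window: int = 60) -> GpsFixSeries:
    """Rolling-median track (MeFF): centre-aligned, edges shrink.

    Applied independently to latitude and longitude of the
    interpolation-completed track; even windows use the midpoint of
    the two central order statistics.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if np.any(rf.missing):
        raise ValueError("median filter requires an interpolation-completed track")
    roll_lat = pd.Series(rf.lat).rolling(window, center=True, min_periods=1).median()
    roll_lon = pd.Series(rf.lon).rolling(window, center=True, min_periods=1).median()
    return GpsFixSeries(rf.time.copy(), roll_lat.to_numpy(), roll_lon.to_numpy(),
                        np.zeros(len(rf), dtype=bool),
                        rf.interpolated.copy())


def flag_jitter_outliers(rf: GpsFixSeries, meff: GpsFixSeries,
                         z: float = 100.0,
                         radius: float = EARTH_RADIUS_M) -> JitterSeries:
    """Per-second RF-to-MeFF distance; seconds above Z are outliers."""
    if len(rf) != len(meff):
        raise ValueError("RF and MeFF series must have the same length")
    dist = _haversine_allow_nan(rf.lat, rf.lon, meff.lat, meff.lon, radius)
    return JitterSeries(rf.time.copy(), dist, dist > z)
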