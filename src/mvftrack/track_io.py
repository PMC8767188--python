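"""Reading, gridding and writing of GPS / accelerometer streams.

GPS fixes are materialised on a contiguous 1 s grid from first to last
timestamp, with absent seconds flagged missing; accelerometer samples
stay at their native rate (nominally 40 Hz) and are reduced to 1 Hz
only at alignment time.  Missing positional fields are written as the
literal ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Per-second label explaining each MVF decision.
REASONS = (
    "moving",       # passed every screen: MVF = 1
    "both_below",   # VeDBA < X and speed < Y
    "speed_only",   # speed >= Y but VeDBA < X (locational-error signature)
    "vedba_only",   # VeDBA >= X but speed < Y (stationary behaviour)
    "too_short",    # both thresholds met but run shorter than T
    "outlier_z",    # RF-to-MeFF distance above Z
    "missing",      # no usable position / speed / VeDBA this second
)

#: Reasons that reflect the behavioural screens (used for breakdowns;
#: missing and outlier seconds are reported separately).
BEHAVIOURAL_REASONS = ("both_below", "speed_only", "vedba_only", "too_short")

#: Column order of the aligned-track CSV.
TRACK_COLUMNS = (
    "time", "lat", "lon", "vedba", "speed", "jitter_dist",
    "pitch", "roll", "mvf", "reason",
)


@dataclass
class GpsFixSeries:
    """GPS fixes on a contiguous 1 s grid.

    ``lat``/``lon`` are decimal degrees (WGS-84); slots with no fix
    hold NaN and are flagged in ``missing``.  ``interpolated`` marks
    slots filled later by :func:`mvftrack.gps_kinematics.interpolate_missing`.
    """

    time: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    missing: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]
    dop: np.ndarray | None = None
    n_sats: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.int64)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.time), dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.time)
        if not all(len(a) == n for a in (self.lat, self.lon, self.missing, self.interpolated)):
            raise ValueError("GpsFixSeries field lengths differ")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("timestamps must be strictly increasing")
        ok = ~self.missing
        if np.any(~np.isfinite(self.lat[ok])) or np.any(~np.isfinite(self.lon[ok])):
            raise ValueError("non-missing slots must have finite coordinates")
        if np.any(np.abs(self.lat[ok]) > 90):
            raise ValueError("latitude out of [-90, 90]")
        if np.any((self.lon[ok] < -180) | (self.lon[ok] >= 180)):
            raise ValueError("longitude out of [-180, 180)")
    def __len__(self) -> int:
        return len(self.time)


@dataclass
class TriaxialAccelSeries:
    """Raw tri-axial acceleration in g, device frame.

    Axis convention: x = surge, y = sway, z = heave with +z up when
    the collar sits upright.
    """

    time: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    nominal_rate: float = 40.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("ax", "ay", "az"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        if not all(len(getattr(self, a)) == n for a in ("ax", "ay", "az")):
            raise ValueError("TriaxialAccelSeries field lengths differ")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be > 0")
        if n > 1 and np.any(np.diff(self.time) < 0):
            raise ValueError("timestamps must be non-decreasing")
        for name in ("ax", "ay", "az"):
            if np.any(~np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite samples in {name}")

    def __len__(self) -> int:
        return len(self.time)

    def samples_per_second(self) -> pd.Series:
        """Sample count per integer second (index = second)."""
        sec = np.floor(self.time).astype(np.int64)
        return pd.Series(1, index=sec).groupby(level=0).sum()

    def undersampled_seconds(self, min_coverage: float = 0.5) -> np.ndarray:
        """Seconds holding fewer than ``min_coverage * nominal_rate`` samples."""
        counts = self.samples_per_second()
        return counts.index.values[counts.values < min_coverage * self.nominal_rate]


def _parse_times(raw: pd.Series, source: str) -> np.ndarray:
    """Accept numeric epoch seconds or datetime strings."""
    num = pd.to_numeric(raw, errors="coerce")
    if num.notna().all():
        return num.to_numpy(dtype=float)
    try:
        ts = pd.to_datetime(raw, utc=True, format="mixed")
    except (ValueError, TypeError) as exc:
        bad = num.index[num.isna()][0]
        raise ValueError(f"{source}: unparsable timestamp at data line {bad + 2}") from exc
    return ts.astype("int64").to_numpy() / 1e9


def _numeric_column(df: pd.DataFrame, col: str, source: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        raise ValueError(
            f"{source}: non-numeric value in column {col!r} at data line "
            f"{int(bad.idxmax()) + 2}"
        )
    return vals.to_numpy(dtype=float)


DEFAULT_GPS_COLUMNS = {"time": "time", "lat": "lat", "lon": "lon",
                       "dop": "dop", "nsats": "nsats"}
DEFAULT_ACCEL_COLUMNS = {"time": "time", "ax": "ax", "ay": "ay", "az": "az"}


def read_gps(source, columns: dict | None = None) -> GpsFixSeries:
    """Read a GPS CSV and materialise it on a contiguous 1 s grid.

    Parameters
    ----------
    source : path or file-like
        CSV with at least timestamp, latitude and longitude columns.
    columns : dict, optional
        Mapping from canonical names (``time``, ``lat``, ``lon``,
        ``dop``, ``nsats``) to the file's column names.

    Seconds between the first and last fix with no row are flagged
    missing.  Rows must be strictly increasing in time; out-of-range
    coordinates raise ``ValueError``.
    """
    cols = dict(DEFAULT_GPS_COLUMNS, **(columns or {}))
    name = getattr(source, "name", str(source))
    df = pd.read_csv(source, na_values=["NA"])
    for canon in ("time", "lat", "lon"):
        if cols[canon] not in df.columns:
            raise ValueError(f"{name}: missing required column {cols[canon]!r}")
    if df.empty:
        raise ValueError(f"{name}: empty GPS file")

    t = _parse_times(df[cols["time"]], name)
    lat = _numeric_column(df, cols["lat"], name)
    lon = _numeric_column(df, cols["lon"], name)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"{name}: non-monotonic timestamp at data line {bad + 2}")
    if np.any(np.abs(lat) > 90):
        bad = int(np.argmax(np.abs(lat) > 90))
        raise ValueError(f"{name}: latitude out of range at data line {bad + 2}")
    if np.any((lon < -180) | (lon >= 180)):
        bad = int(np.argmax((lon < -180) | (lon >= 180)))
        raise ValueError(f"{name}: longitude out of range at data line {bad + 2}")

    sec = np.floor(t).astype(np.int64)
    # Nominal 1 Hz: keep the first fix landing in any one second.
    keep = np.concatenate([[True], np.diff(sec) > 0])
    sec, lat, lon = sec[keep], lat[keep], lon[keep]

    grid = np.arange(sec[0], sec[-1] + 1, dtype=np.int64)
    idx = sec - sec[0]
    glat = np.full(len(grid), np.nan)
    glon = np.full(len(grid), np.nan)
    glat[idx], glon[idx] = lat, lon
    missing = np.ones(len(grid), dtype=bool)
    missing[idx] = False

    extras = {}
    for canon, attr in (("dop", "dop"), ("nsats", "n_sats")):
        if cols[canon] in df.columns:
            vals = _numeric_column(df, cols[canon], name)[keep]
            full = np.full(len(grid), np.nan)
            full[idx] = vals
            extras[attr] = full
    return GpsFixSeries(grid, glat, glon, missing, **extras)


def read_accel(source, nominal_rate: float = 40.0,
               columns: dict | None = None) -> TriaxialAccelSeries:
    """Read a tri-axial accelerometer CSV (time, ax, ay, az in g)."""
    cols = dict(DEFAULT_ACCEL_COLUMNS, **(columns or {}))
    name = getattr(source, "name", str(source))
    df = pd.read_csv(source)
    if df.empty:
        raise ValueError(f"{name}: empty accelerometer file")
    for canon in ("time", "ax", "ay", "az"):
        if cols[canon] not in df.columns:
            raise ValueError(f"{name}: missing required column {cols[canon]!r}")
    t = _parse_times(df[cols["time"]], name)
    axes = [_numeric_column(df, cols[a], name) for a in ("ax", "ay", "az")]
    order = np.argsort(t, kind="stable")
    return TriaxialAccelSeries(t[order], axes[0][order], axes[1][order],
                               axes[2][order], nominal_rate=nominal_rate)


def align_1hz(gps: GpsFixSeries, accel_time: np.ndarray, vedba_s: np.ndarray,
              pitch: np.ndarray, roll: np.ndarray,
              nominal_rate: float = 40.0,
              min_coverage: float = 0.5) -> pd.DataFrame:
    """Fuse GPS and per-sample accelerometer features onto a 1 Hz grid.

    Accelerometer-derived fields are averaged within each integer
    second; seconds holding fewer than ``min_coverage * nominal_rate``
    samples yield missing VeDBA.  GPS fields are carried from the fix
    at that second.  Returns one record per second of the overlap with
    columns ``time, lat, lon, vedba, pitch, roll``.
    """
    accel_time = np.asarray(accel_time, dtype=float)
    sec = np.floor(accel_time).astype(np.int64)
    per_sec = pd.DataFrame({"sec": sec, "vedba": vedba_s,
                            "pitch": pitch, "roll": roll})
    agg = per_sec.groupby("sec").agg(vedba=("vedba", "mean"),
                                     pitch=("pitch", "mean"),
                                     roll=("roll", "mean"),
                                     n=("vedba", "size"))
    agg.loc[agg["n"] < min_coverage * nominal_rate,
            ["vedba", "pitch", "roll"]] = np.nan

    t0 = max(int(gps.time[0]), int(agg.index.min()))
    t1 = min(int(gps.time[-1]), int(agg.index.max()))
    if t1 < t0:
        raise ValueError("GPS and accelerometer streams do not overlap in time")
    grid = np.arange(t0, t1 + 1, dtype=np.int64)

    gsl = slice(t0 - int(gps.time[0]), t0 - int(gps.time[0]) + len(grid))
    track = pd.DataFrame({
        "time": grid,
        "lat": gps.lat[gsl],
        "lon": gps.lon[gsl],
        "vedba": agg["vedba"].reindex(grid).to_numpy(),
        "pitch": agg["pitch"].reindex(grid).to_numpy(),
        "roll": agg["roll"].reindex(grid).to_numpy(),
    })
    return track


def write_track(track: pd.DataFrame, path) -> None:
    """Write an aligned track CSV; missing values become ``NA``.

    Coordinates are kept to six decimal places (finer than the ~1.1 m
    resolution of the fifth decimal place); other numeric fields to
    four or five.
    """
    out = track.copy()
    for col, nd in (("lat", 6), ("lon", 6), ("vedba", 5), ("speed", 4),
                    ("jitter_dist", 3), ("pitch", 3), ("roll", 3)):
        if col in out.columns:
            out[col] = out[col].round(nd)
    cols = [c for c in TRACK_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False, na_rep="NA")


def read_track(path) -> pd.DataFrame:
    """Read a track CSV written by :func:`write_track`."""
    df = pd.read_csv(path, na_values=["NA"])
    if "mvf" in df.columns:
        df["mvf"] = df["mvf"].astype("Int64")
    return df


def write_gps_csv(fixes: GpsFixSeries, path, decimals: int = 6) -> None:
    """Write non-missing fixes as a plain GPS CSV (time, lat, lon)."""
    ok = ~fixes.missing
    df = pd.DataFrame({"time": fixes.time[ok],
                       "lat": np.round(fixes.lat[ok], decimals),
                       "lon": np.round(fixes.lon[ok], decimals)})
    df.to_csv(path, index=False)


def write_accel_csv(accel: TriaxialAccelSeries, path) -> None:
    """Write an accelerometer CSV (time to ms, axes to 5 dp)."""
    df = pd.DataFrame({"time": np.round(accel.time, 3),
                       "ax": np.round(accel.ax, 5),
                       "ay": np.round(accel.ay, 5),
                       "az": np.round(accel.az, 5)})
    df.to_csv(path, index=False)
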