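"""The MVF decision tree: per-second movement verification.

Each second of the aligned track receives an MVF label (1 = verified
travelling, 0 = everything else) and exactly one reason code.
Precedence: a missing position/speed/VeDBA wins, then the Z-threshold
outlier screen, then the joint VeDBA (X) and GPS-speed (Y) thresholds,
then the minimum-duration screen (T).  Qualifying runs separated by at
most ``merge_gap`` seconds are merged after the T screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accel_features import compute_vedba, pitch_roll
from .config import MvfConfig
from .gps_kinematics import (JitterSeries, derive_speed, flag_jitter_outliers,
                             interpolate_missing, median_filter_track)
from .track_io import (BEHAVIOURAL_REASONS, GpsFixSeries, TriaxialAccelSeries,
                       align_1hz)


def _runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs (stop exclusive)."""
    if mask.size == 0:
        return
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e)


def classify_movement(track: pd.DataFrame, jitter: JitterSeries,
                      cfg: MvfConfig | None = None) -> pd.DataFrame:
    """Fill ``mvf`` and ``reason`` columns of an aligned track.

    ``track`` must carry ``vedba`` and ``speed`` columns (smoothed, on
    the 1 Hz grid); ``jitter`` must cover the same seconds.  The input
    frame is not modified; a labelled copy is returned.
    """
    cfg = cfg or MvfConfig()
    for col in ("vedba", "speed"):
        if col not in track.columns:
            raise ValueError(f"track is missing the {col!r} column")
    if len(jitter) != len(track) or not np.array_equal(
            np.asarray(jitter.time), track["time"].to_numpy()):
        raise ValueError("track and jitter series are not aligned")

    out = track.copy()
    n = len(out)
    vedba = out["vedba"].to_numpy(dtype=float)
    speed = out["speed"].to_numpy(dtype=float)
    pos_missing = ~np.isfinite(out["lat"].to_numpy(dtype=float))

    missing = pos_missing | ~np.isfinite(vedba) | ~np.isfinite(speed)
    outlier = ~missing & np.asarray(jitter.outlier, dtype=bool)
    evaluable = ~missing & ~outlier

    # Pass-inclusive thresholds: equality counts as meeting X / Y.
    hi_v = evaluable & (vedba >= cfg.x_vedba)
    hi_s = evaluable & (speed >= cfg.y_speed)
    candidate = hi_v & hi_s

    reason = np.empty(n, dtype=object)
    reason[missing] = "missing"
    reason[outlier] = "outlier_z"
    reason[evaluable & ~hi_v & ~hi_s] = "both_below"
    reason[evaluable & ~hi_v & hi_s] = "speed_only"
    reason[evaluable & hi_v & ~hi_s] = "vedba_only"

    mvf = np.zeros(n, dtype=np.int64)
    for s, e in _runs(candidate):
        if e - s >= cfg.t_min:
            mvf[s:e] = 1
            reason[s:e] = "moving"
        else:
            reason[s:e] = "too_short"

    # Merge MVF=1 runs separated by <= merge_gap seconds.
    runs = list(_runs(mvf == 1))
    for (s1, e1), (s2, e2) in zip(runs[:-1], runs[1:]):
        if s2 - e1 <= cfg.merge_gap:
            mvf[e1:s2] = 1
            reason[e1:s2] = "moving"

    out["mvf"] = mvf
    out["reason"] = reason
    return out


def segment_bouts(track: pd.DataFrame,
                  radius: float = 6_371_000.0) -> pd.DataFrame:
    """Maximal runs of constant MVF value as a bout table.

    Columns: start, end (inclusive timestamps), state, duration_s,
    distance_m, mean_speed, straightness.  Distance and straightness
    come from the bout's non-missing fixes; mean_speed is the mean of
    the smoothed GPS speed over the bout's valid seconds.
    """
    from .movement_metrics import straightness_index

    cols = ["start", "end", "state", "duration_s", "distance_m",
            "mean_speed", "straightness"]
    if len(track) == 0:
        return pd.DataFrame(columns=cols)
    if "mvf" not in track.columns:
        raise ValueError("track has no mvf labels; run classify_movement first")

    t = track["time"].to_numpy()
    mvf = track["mvf"].to_numpy(dtype=np.int64)
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    speed = track["speed"].to_numpy(dtype=float) if "speed" in track.columns \
        else np.full(len(track), np.nan)

    from .gps_kinematics import _haversine_allow_nan

    rows = []
    change = np.flatnonzero(np.diff(mvf)) + 1
    bounds = np.concatenate([[0], change, [len(track)]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        s, e = int(s), int(e)
        blat, blon = lat[s:e], lon[s:e]
        ok = np.isfinite(blat)
        dist = 0.0
        straight = np.nan
        if ok.sum() >= 2:
            plat, plon = blat[ok], blon[ok]
            steps = _haversine_allow_nan(plat[:-1], plon[:-1],
                                         plat[1:], plon[1:], radius)
            dist = float(np.sum(steps))
            straight = straightness_index(plat, plon, radius)
        sp = speed[s:e]
        rows.append({
            "start": t[s], "end": t[e - 1],
            "state": "moving" if mvf[s] == 1 else "non-moving",
            "duration_s": int(e - s),
            "distance_m": dist,
            "mean_speed": float(np.nanmean(sp)) if np.any(np.isfinite(sp)) else np.nan,
            "straightness": straight,
        })
    return pd.DataFrame(rows, columns=cols)


def reason_breakdown(track: pd.DataFrame) -> dict:
    """Fractions of non-moving seconds per behavioural reason.

    The four behavioural reasons (both_below, speed_only, vedba_only,
    too_short) are normalised to sum to 1 over the non-moving seconds
    that were actually evaluable; missing and outlier seconds are
    reported separately as fractions of all seconds.
    """
    if "reason" not in track.columns:
        raise ValueError("track has no reason codes; run classify_movement first")
    reason = track["reason"]
    n = len(track)
    counts = {r: int((reason == r).sum()) for r in BEHAVIOURAL_REASONS}
    total = sum(counts.values())
    out = {r: (c / total if total else np.nan) for r, c in counts.items()} \
        if total else {}
    out["missing_fraction"] = float((reason == "missing").sum() / n) if n else np.nan
    out["outlier_fraction"] = float((reason == "outlier_z").sum() / n) if n else np.nan
    return out


def run_pipeline(gps: GpsFixSeries, accel: TriaxialAccelSeries,
                 cfg: MvfConfig | None = None) -> pd.DataFrame:
    """Full MVF pipeline: raw streams in, labelled aligned track out.

    Stages: VeDBA derivation and smoothing; posture angles; linear
    interpolation of missing fixes (RF); rolling-median track (MeFF)
    and Z-threshold outlier flags; stepping-range GPS speed; 1 Hz
    fusion; MVF classification.  Returns the aligned track with
    columns time, lat, lon, vedba, speed, jitter_dist, pitch, roll,
    mvf, reason.
    """
    cfg = cfg or MvfConfig()

    ved = compute_vedba(accel, cfg.static_window, cfg.vedba_smooth)
    pitch, roll = pitch_roll(ved.static_x, ved.static_y, ved.static_z)

    rf = interpolate_missing(gps)
    meff = median_filter_track(rf, cfg.median_window)
    jitter_full = flag_jitter_outliers(rf, meff, cfg.z_dist, cfg.earth_radius)
    speed_full = derive_speed(gps, cfg.stepping_range, cfg.speed_smooth,
                              cfg.earth_radius)

    track = align_1hz(gps, accel.time, ved.vedba_s, pitch, roll,
                      nominal_rate=accel.nominal_rate,
                      min_coverage=cfg.min_accel_coverage)

    grid = track["time"].to_numpy()
    offset = int(grid[0] - gps.time[0])
    sl = slice(offset, offset + len(grid))
    track["speed"] = speed_full.speed_s[sl]
    track["jitter_dist"] = jitter_full.jitter_dist[sl]
    jitter = JitterSeries(grid, jitter_full.jitter_dist[sl],
                          jitter_full.outlier[sl])
    return classify_movement(track, jitter, cfg)
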