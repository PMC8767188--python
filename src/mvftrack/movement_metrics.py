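"""Before/after-filtering movement summaries and validation metrics.

Covers cumulative distance and speed by movement state (optionally by
clock hour), the bout-level straightness (tortuosity) index, ethogram
confusion evaluation, and the OLS regression of per-bout GPS speed on
per-bout VeDBA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gps_kinematics import EARTH_RADIUS_M, _haversine_allow_nan, haversine


@dataclass
class ConfusionSummary:
    """Per-second confusion counts and rates (percent) vs an ethogram.

    Rates follow the standard contingency formulas:
    TPR = TP/(TP+FN)·100, FNR = FN/(FN+TP)·100,
    FPR = FP/(FP+TN)·100, TNR = TN/(TN+FP)·100,
    accuracy = (TP+TN)/(TP+TN+FP+FN)·100.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion summary needs at least one labelled second")

    @property
    def tpr(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else np.nan

    @property
    def fnr(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.fn / pos if pos else np.nan

    @property
    def fpr(self) -> float:
        neg = self.fp + self.tn
        return 100.0 * self.fp / neg if neg else np.nan

    @property
    def tnr(self) -> float:
        neg = self.fp + self.tn
        return 100.0 * self.tn / neg if neg else np.nan

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.tp + self.tn) / total

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "tpr": self.tpr, "fpr": self.fpr, "tnr": self.tnr,
                "fnr": self.fnr, "accuracy": self.accuracy}


@dataclass
class RegressionFit:
    """OLS fit y = a + b·x of per-bout mean speed on per-bout mean VeDBA."""

    intercept: float
    slope: float
    r_squared: float
    n: int


def _state_mask(track: pd.DataFrame, state: str) -> np.ndarray:
    """Second-selection mask for a movement-state filter.

    ``moving`` selects MVF=1 seconds; ``non-moving`` selects MVF=0
    seconds that failed on behavioural grounds (missing positions and
    Z-threshold outliers are excluded from the non-moving class);
    ``all`` selects every second.
    """
    if state == "all":
        return np.ones(len(track), dtype=bool)
    if "mvf" not in track.columns:
        raise ValueError("track has no mvf labels")
    mvf = track["mvf"].to_numpy(dtype=float)
    if state == "moving":
        return mvf == 1
    if state == "non-moving":
        reason = track["reason"].to_numpy(dtype=object)
        return (mvf == 0) & ~np.isin(reason, ["missing", "outlier_z"])
    raise ValueError(f"unknown state filter {state!r}")


def path_metrics(track: pd.DataFrame, state: str = "all",
                 grouping: str = "none",
                 radius: float = EARTH_RADIUS_M) -> pd.DataFrame:
    """Cumulative distance and speed summary for a movement state.

    Distance sums Haversine steps between successive non-missing fixes
    within each maximal run of selected seconds.  With
    ``grouping="hourly"`` steps and speeds are binned by clock hour
    (0–23) of the step's starting second; hourly distances sum to the
    ungrouped total by construction.

    Returns a frame with columns ``group, distance_m, mean_speed,
    max_speed, n_seconds, defined`` (``defined`` is False where the
    selection holds no valid speed second).
    """
    if grouping not in ("none", "hourly"):
        raise ValueError(f"unknown grouping {grouping!r}")
    sel = _state_mask(track, state)
    t = track["time"].to_numpy()
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    speed = track["speed"].to_numpy(dtype=float) if "speed" in track.columns \
        else np.full(len(track), np.nan)

    step_hours: list[np.ndarray] = []
    step_dists: list[np.ndarray] = []
    idx = np.flatnonzero(sel)
    if idx.size:
        run_starts = np.flatnonzero(np.concatenate([[True], np.diff(idx) > 1]))
        run_bounds = np.concatenate([run_starts, [idx.size]])
        for a, b in zip(run_bounds[:-1], run_bounds[1:]):
            run = idx[a:b]
            ok = run[np.isfinite(lat[run])]
            if ok.size >= 2:
                d = _haversine_allow_nan(lat[ok[:-1]], lon[ok[:-1]],
                                         lat[ok[1:]], lon[ok[1:]], radius)
                step_dists.append(d)
                step_hours.append((t[ok[:-1]] // 3600) % 24)
    dists = np.concatenate(step_dists) if step_dists else np.array([])
    hours = np.concatenate(step_hours) if step_hours else np.array([], dtype=np.int64)

    sp = speed[sel]
    sp_hours = (t[sel] // 3600) % 24
    rows = []
    if grouping == "none":
        groups = [("all", np.ones(len(dists), dtype=bool),
                   np.ones(sel.sum(), dtype=bool))]
    else:
        groups = [(h, hours == h, sp_hours == h)
                  for h in np.unique(np.concatenate([hours, sp_hours]))]
    for g, dmask, smask in groups:
        gsp = sp[smask]
        has_speed = np.any(np.isfinite(gsp))
        rows.append({
            "group": g,
            "distance_m": float(dists[dmask].sum()) if len(dists) else 0.0,
            "mean_speed": float(np.nanmean(gsp)) if has_speed else np.nan,
            "max_speed": float(np.nanmax(gsp)) if has_speed else np.nan,
            "n_seconds": int(smask.sum()),
            "defined": bool(has_speed),
        })
    return pd.DataFrame(rows, columns=["group", "distance_m", "mean_speed",
                                       "max_speed", "n_seconds", "defined"])


def straightness_index(lat, lon, radius: float = EARTH_RADIUS_M) -> float:
    """Net displacement over cumulative path length, in [0, 1].

    1 for dead-straight travel, tending to 0 for closed loops.
    Returns NaN (undefined) when the cumulative path length is zero or
    fewer than two fixes are given.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    ok = np.isfinite(lat) & np.isfinite(lon)
    lat, lon = lat[ok], lon[ok]
    if len(lat) < 2:
        return np.nan
    steps = _haversine_allow_nan(lat[:-1], lon[:-1], lat[1:], lon[1:], radius)
    gross = float(np.sum(steps))
    if gross == 0.0:
        return np.nan
    net = haversine(lat[0], lon[0], lat[-1], lon[-1], radius)
    return min(1.0, net / gross)


def evaluate_confusion(predicted, truth) -> ConfusionSummary:
    """Confusion summary of per-second MVF labels against an ethogram.

    ``predicted`` holds MVF values in {0, 1}; ``truth`` holds
    ``"moving"`` / ``"non-moving"`` strings (or booleans).  Seconds
    with no ethogram label (NaN/None/empty) are excluded.
    """
    pred = pd.Series(predicted).to_numpy()
    tru = pd.Series(truth)
    if len(pred) != len(tru):
        raise ValueError("predicted and truth must have equal length")
    if tru.dtype == object or str(tru.dtype).startswith("str"):
        labelled = tru.notna() & (tru.astype(str).str.len() > 0)
        tru_bool = tru.astype(str).str.strip().str.lower().isin(
            ["moving", "1", "true"]).to_numpy()
    else:
        labelled = tru.notna()
        tru_bool = tru.fillna(False).astype(bool).to_numpy()
    labelled = labelled.to_numpy() & pd.Series(pred).notna().to_numpy()
    if not labelled.any():
        raise ValueError("no labelled seconds to evaluate")
    p = pred[labelled].astype(float) == 1
    y = tru_bool[labelled]
    return ConfusionSummary(tp=int(np.sum(p & y)), fp=int(np.sum(p & ~y)),
                            tn=int(np.sum(~p & ~y)), fn=int(np.sum(~p & y)))


def average_rates(summaries) -> dict:
    """Unweighted mean of rates across per-individual summaries.

    Mirrors reporting that averages each individual's TPR/FPR/TNR/FNR
    and accuracy rather than pooling the second counts.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to average")
    keys = ("tpr", "fpr", "tnr", "fnr", "accuracy")
    return {k: float(np.nanmean([getattr(s, k) for s in summaries]))
            for k in keys}


def speed_vedba_regression(bouts: pd.DataFrame,
                           track: pd.DataFrame) -> RegressionFit:
    """OLS of per-bout mean GPS speed on per-bout mean VeDBA.

    Uses moving bouts only; each data point is one bout's mean of the
    smoothed speed and smoothed VeDBA over its seconds.
    """
    moving = bouts[bouts["state"] == "moving"]
    if len(moving) < 2:
        raise ValueError("need at least two moving bouts")
    t = track["time"].to_numpy()
    vedba = track["vedba"].to_numpy(dtype=float)
    speed = track["speed"].to_numpy(dtype=float)
    xs, ys = [], []
    for _, b in moving.iterrows():
        m = (t >= b["start"]) & (t <= b["end"])
        if np.any(np.isfinite(vedba[m])) and np.any(np.isfinite(speed[m])):
            xs.append(np.nanmean(vedba[m]))
            ys.append(np.nanmean(speed[m]))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 2 or np.ptp(xs) == 0:
        raise ValueError("degenerate fit: no variance in per-bout VeDBA means")
    fit = stats.linregress(xs, ys)
    return RegressionFit(intercept=float(fit.intercept), slope=float(fit.slope),
                         r_squared=float(fit.rvalue ** 2), n=len(xs))
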