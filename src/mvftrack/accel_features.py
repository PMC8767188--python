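"""VeDBA and static-posture angles from raw tri-axial acceleration.

The static (gravitational) component of each axis is estimated with a
centre-aligned rolling mean; the dynamic component is the residual.
VeDBA — vectorial dynamic body acceleration — is the Euclidean norm of
the dynamic vector, subsequently smoothed with a centre-aligned
rolling mean (2 s by default) so that acceleration and deceleration
phases of a stride cycle fall in one window.  Pitch and roll come from
the static vector under the collar convention x = surge, y = sway,
z = heave (+z up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track_io import TriaxialAccelSeries


@dataclass
class VedbaSeries:
    """Per-sample raw and smoothed VeDBA, plus the static vector."""

    time: np.ndarray
    vedba_raw: np.ndarray
    vedba_s: np.ndarray
    static_x: np.ndarray
    static_y: np.ndarray
    static_z: np.ndarray

    def __len__(self) -> int:
        return len(self.time)


def rolling_stat(values, window: int, stat: str = "mean") -> np.ndarray:
    """Centre-aligned rolling mean or median with edge shrink.

    At the edges the window shrinks to the available samples, so the
    output has the same length as the input.  NaN inputs are excluded
    from each window's statistic.  Even windows take the extra sample
    on the left of centre.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown stat {stat!r}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    roll = pd.Series(values).rolling(window, center=True, min_periods=1)
    out = roll.mean() if stat == "mean" else roll.median()
    return out.to_numpy()


def compute_vedba(accel: TriaxialAccelSeries,
                  static_window: float = 2.0,
                  smooth_window: float = 2.0) -> VedbaSeries:
    """Derive raw and smoothed VeDBA from a tri-axial series.

    Parameters
    ----------
    accel : TriaxialAccelSeries
        Raw acceleration in g at the device's native rate.
    static_window, smooth_window : float
        Window lengths in seconds for, respectively, the per-axis
        static (gravity) estimate and the VeDBA post-smoothing.
    """
    if static_window <= 0 or smooth_window <= 0:
        raise ValueError("windows must be > 0 seconds")
    if len(accel) == 0:
        raise ValueError("empty acceleration series")
    w_static = max(1, round(static_window * accel.nominal_rate))
    w_smooth = max(1, round(smooth_window * accel.nominal_rate))

    sx = rolling_stat(accel.ax, w_static)
    sy = rolling_stat(accel.ay, w_static)
    sz = rolling_stat(accel.az, w_static)
    dx, dy, dz = accel.ax - sx, accel.ay - sy, accel.az - sz
    vedba_raw = np.sqrt(dx * dx + dy * dy + dz * dz)
    vedba_s = rolling_stat(vedba_raw, w_smooth)
    return VedbaSeries(accel.time, vedba_raw, vedba_s, sx, sy, sz)


def pitch_roll(static_x, static_y, static_z) -> tuple[np.ndarray, np.ndarray]:
    """Posture angles, in degrees, from the static acceleration vector.

    pitch = atan2(-x, sqrt(y² + z²)) ∈ [-90, 90];
    roll  = atan2(y, z) ∈ (-180, 180].
    Zero-norm static vectors yield NaN for both angles.
    """
    x = np.asarray(static_x, dtype=float)
    y = np.asarray(static_y, dtype=float)
    z = np.asarray(static_z, dtype=float)
    norm = np.sqrt(x * x + y * y + z * z)
    pitch = np.degrees(np.arctan2(-x, np.hypot(y, z)))
    roll = np.degrees(np.arctan2(y, z))
    bad = ~(norm > 0)
    pitch = np.where(bad, np.nan, pitch)
    roll = np.where(bad, np.nan, roll)
    return pitch, roll
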