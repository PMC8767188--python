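"""MVF threshold configuration.

All tunables of the movement-verified filtering protocol live in
:class:`MvfConfig`.  Defaults are the lion calibration: VeDBA threshold
X = 0.11 g, GPS-speed threshold Y = 0.35 m s⁻¹, minimum movement
duration T = 5 s, outlier distance Z = 100 m, a 60 s rolling-median
window for the outlier screen, a five-fix stepping range with 5 s
post-smoothing for GPS speed, and 2 s windows for the static
(gravity) estimate and VeDBA smoothing.

Configs round-trip through a flat ``key = value`` text file; ``#``
starts a comment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class MvfConfig:
    """Thresholds and window lengths of the MVF protocol.

    Attributes
    ----------
    x_vedba : float
        VeDBA movement threshold X, in g.
    y_speed : float
        GPS-speed movement threshold Y, in m s⁻¹.
    t_min : int
        Minimum uninterrupted duration T, in seconds, for which both X
        and Y must be met before seconds are labelled moving.
    z_dist : float
        Outlier threshold Z, in metres, on the distance between the
        interpolation-completed track (RF) and its rolling-median
        counterpart (MeFF).
    median_window : int
        Rolling-median window, in seconds, used to build MeFF.
    stepping_range : int
        Interval, in retained fixes, between the positions used for
        each distance/speed computation.
    speed_smooth : int
        Centre-aligned rolling-mean window, in seconds, applied to the
        stepping-range GPS speed.
    vedba_smooth : float
        Centre-aligned rolling-mean window, in seconds, applied to raw
        VeDBA.
    static_window : float
        Rolling-mean window, in seconds, for the static (gravity)
        acceleration estimate.
    merge_gap : int
        MVF=1 runs separated by at most this many seconds are merged.
    earth_radius : float
        Sphere radius, in metres, for Haversine distances.
    min_accel_coverage : float
        Fraction of the nominal per-second sample count below which an
        accelerometer second is treated as missing.
    """

    x_vedba: float = 0.11
    y_speed: float = 0.35
    t_min: int = 5
    z_dist: float = 100.0
    median_window: int = 60
    stepping_range: int = 5
    speed_smooth: int = 5
    vedba_smooth: float = 2.0
    static_window: float = 2.0
    merge_gap: int = 2
    earth_radius: float = 6_371_000.0
    min_accel_coverage: float = 0.5

    _INT_FIELDS = ("t_min", "median_window", "stepping_range", "speed_smooth", "merge_gap")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "merge_gap":
                if v < 0:
                    raise ValueError("merge_gap must be >= 0")
            elif f.name == "min_accel_coverage":
                if not 0.0 < v <= 1.0:
                    raise ValueError("min_accel_coverage must be in (0, 1]")
            elif v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")
        if self.t_min < 1:
            raise ValueError("t_min must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "MvfConfig":
        """Load a config from a flat ``key = value`` file.

        Keyword ``overrides`` take precedence over file values.
        Unknown keys raise ``ValueError`` naming the key.
        """
        known = {f.name for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            try:
                values[key] = int(val) if key in cls._INT_FIELDS else float(val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value for {key!r}: {val!r}") from exc
        values.update(overrides)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
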