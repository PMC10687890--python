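"""Trajectory container and CSV dialect.

Timestamps are UTC; coordinates are projected meters.  The CSV dialect is
``animal_id, timestamp (ISO-8601), x, y`` with an optional ``error_sd``
column for per-fix location error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from contactrsf.errors import InvalidArgumentError


@dataclass
class Trajectory:
    """One animal's timestamped positions.

    ``times`` is a numpy ``datetime64[ns]`` array, strictly increasing;
    ``regular``/``interval_min`` flag an evenly gridded (interpolated) track.
    """

    animal_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    error_sd: np.ndarray | None = None
    regular: bool = False
    interval_min: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.error_sd is not None:
            self.error_sd = np.asarray(self.error_sd, dtype=float)
            if len(self.error_sd) != len(self.times):
                raise InvalidArgumentError("error_sd length mismatch")
        n = len(self.times)
        if len(self.x) != n or len(self.y) != n:
            raise InvalidArgumentError("times, x, y must have equal length")
        if n == 0:
            raise InvalidArgumentError("empty trajectory")
        if n > 1 and not (np.diff(self.times.astype("int64")) > 0).all():
            raise InvalidArgumentError("timestamps must be strictly increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise InvalidArgumentError("coordinates must be finite")
        if self.regular and self.interval_min is None:
            raise InvalidArgumentError("regular track needs interval_min")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def t_seconds(self) -> np.ndarray:
        """Times as float seconds since the Unix epoch."""
        return self.times.astype("int64") / 1e9

    @property
    def start(self) -> np.datetime64:
        return self.times[0]

    @property
    def end(self) -> np.datetime64:
        return self.times[-1]

    @property
    def dates(self) -> np.ndarray:
        """Calendar day (UTC) of each fix."""
        return self.times.astype("datetime64[D]")

    def window(self, start, end) -> "Trajectory":
        """Subset of fixes with ``start <= t <= end`` (closed interval)."""
        start = np.datetime64(pd.Timestamp(start).to_datetime64())
        end = np.datetime64(pd.Timestamp(end).to_datetime64())
        mask = (self.times >= start) & (self.times <= end)
        if not mask.any():
            raise InvalidArgumentError("window contains no fixes")
        return Trajectory(
            animal_id=self.animal_id,
            times=self.times[mask],
            x=self.x[mask],
            y=self.y[mask],
            error_sd=None if self.error_sd is None else self.error_sd[mask],
            regular=self.regular,
            interval_min=self.interval_min,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "timestamp": pd.DatetimeIndex(self.times, tz="UTC"),
                "x": self.x,
                "y": self.y,
            }
        )
        if self.error_sd is not None:
            df["error_sd"] = self.error_sd
        return df


def write_tracks_csv(tracks: list[Trajectory], path) -> Path:
    path = Path(path)
    frames = [t.to_frame() for t in tracks]
    df = pd.concat(frames, ignore_index=True)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3] + "Z"
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_tracks_csv(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    required = {"animal_id", "timestamp", "x", "y"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"tracks CSV must have columns {sorted(required)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    df = df.assign(_ts=ts.dt.tz_localize(None))
    tracks = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("_ts")
        tracks.append(
            Trajectory(
                animal_id=str(animal_id),
                times=sub["_ts"].to_numpy(),
                x=sub["x"].to_numpy(),
                y=sub["y"].to_numpy(),
                error_sd=sub["error_sd"].to_numpy() if "error_sd" in sub else None,
            )
        )
    return tracks
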