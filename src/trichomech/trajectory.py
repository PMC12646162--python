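"""Time-stamped 2-D position traces of a tracked object.

The pipeline's central observable is the position of a micropipette tip (or a
trichome stalk point) over time, extracted from bright-field video.  Positions
are stored in micrometres, time in seconds.  Frames in which tracking failed
are kept as NaN so downstream fits can exclude them explicitly rather than
interpolate through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrackedTrajectory", "read_trajectory_csv", "write_trajectory_csv"]


@dataclass
class TrackedTrajectory:
    """Positions of one tracked object.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing.
    x, y : array of float
        Positions in micrometres.  NaN marks a missing frame.
    pixel_size : float, optional
        Micrometres per pixel of the source video, if known.
    frame_rate : float, optional
        Nominal acquisition rate in Hz, if known.
    source : str
        Free-text provenance (file name, generator parameters, ...).
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pixel_size: float | None = None
    frame_rate: float | None = None
    source: str = ""
    missing: np.ndarray = field(default=None, repr=False)  # bool mask

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x, y must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.missing is None:
            self.missing = ~(np.isfinite(self.x) & np.isfinite(self.y))
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def valid(self) -> "TrackedTrajectory":
        """Return a copy with missing frames dropped."""
        keep = ~self.missing
        return TrackedTrajectory(
            self.times[keep], self.x[keep], self.y[keep],
            pixel_size=self.pixel_size, frame_rate=self.frame_rate,
            source=self.source,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "x_um": self.x, "y_um": self.y})


def write_trajectory_csv(traj: TrackedTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path, pixel_size: float | None = None,
                        frame_rate: float | None = None) -> TrackedTrajectory:
    df = pd.read_csv(path)
    for col in ("time_s", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"trajectory CSV missing column {col!r} in {path}")
    return TrackedTrajectory(
        df["time_s"].to_numpy(), df["x_um"].to_numpy(), df["y_um"].to_numpy(),
        pixel_size=pixel_size, frame_rate=frame_rate, source=str(path),
    )
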