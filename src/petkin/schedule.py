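"""Acquisition frame schedules for dynamic PET.

A dynamic PET study records counts in a sequence of contiguous (or gapped,
but never overlapping) time frames.  Schedules are specified, as on scanner
consoles, by a list of ``(count, duration)`` pairs, e.g. the blood-flow
protocol ``1 x 1 min, 15 x 2 s, 15 x 5 s, 12 x 10 s, 8 x 15 s, 6 x 20 s``.
Internally everything is kept in seconds; kinetic quantities elsewhere in the
package use minutes, and the schedule exposes minute-valued views for that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FrameSchedule", "build_frame_schedule"]

#: the two acquisition sequences used throughout the worked examples:
#: a water bolus scan (8.75 min) and an FDG infusion scan (61 min).
H2O_FRAMING = [(1, 60.0), (15, 2.0), (15, 5.0), (12, 10.0), (8, 15.0), (6, 20.0)]
FDG_FRAMING = [(1, 60.0), (4, 20.0), (4, 40.0), (4, 60.0), (4, 180.0), (8, 300.0)]


@dataclass(frozen=True)
class FrameSchedule:
    """Sequence of acquisition frames.

    Parameters
    ----------
    start_s : np.ndarray
        Frame start times in seconds, strictly increasing.
    duration_s : np.ndarray
        Frame durations in seconds, all positive.  Frames must not overlap.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValueError("start_s and duration_s must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(start[1:] < (start[:-1] + dur[:-1]) - 1e-9):
            raise ValueError("frames must not overlap")
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)

    # -- basic views ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def total_duration_s(self) -> float:
        """Sum of frame durations (equals span when frames are contiguous)."""
        return float(self.duration_s.sum())

    @property
    def scan_end_min(self) -> float:
        """End of acquisition (minutes) -- the T_E of residue analysis."""
        return float(self.end_s[-1]) / 60.0

    @property
    def start_min(self) -> np.ndarray:
        return self.start_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        return (self.start_s + 0.5 * self.duration_s) / 60.0

    # -- manipulation --------------------------------------------------
    def shift(self, offset_s: float) -> "FrameSchedule":
        return FrameSchedule(self.start_s + offset_s, self.duration_s.copy())

    def subset(self, idx) -> "FrameSchedule":
        idx = np.asarray(idx)
        return FrameSchedule(self.start_s[idx], self.duration_s[idx])

    def concatenate(self, other: "FrameSchedule") -> "FrameSchedule":
        return FrameSchedule(
            np.concatenate([self.start_s, other.start_s]),
            np.concatenate([self.duration_s, other.duration_s]),
        )

    # -- IO ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start_s": self.start_s, "duration_s": self.duration_s})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrameSchedule":
        df = pd.read_csv(path)
        return cls(df["start_s"].to_numpy(), df["duration_s"].to_numpy())


def build_frame_schedule(spec, origin_s: float = 0.0) -> FrameSchedule:
    """Expand a ``(count, duration)`` framing spec into a contiguous schedule.

    Parameters
    ----------
    spec : sequence of (int, float)
        Number of frames and per-frame duration in seconds for each block.
    origin_s : float
        Start time of the first frame.

    Examples
    --------
    >>> sched = build_frame_schedule([(1, 60), (15, 2), (15, 5), (12, 10),
    ...                               (8, 15), (6, 20)])
    >>> sched.n_frames, sched.total_duration_s / 60
    (57, 8.75)
    """
    spec = list(spec)
    if not spec:
        raise ValueError("framing spec must contain at least one (count, duration) block")
    durs = []
    for count, duration in spec:
        count = int(count)
        if count < 1:
            raise ValueError("frame counts must be >= 1")
        if duration <= 0:
            raise ValueError("frame durations must be positive")
        durs.extend([float(duration)] * count)
    durs = np.asarray(durs)
    starts = origin_s + np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    return FrameSchedule(starts, durs)
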