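"""Frame timing of a dynamic PET acquisition.

A :class:`FrameSchedule` is the ordered list of frame start times and
durations (seconds post-injection) that defines both the acquisition
protocol and every analysis window derived from it.  The default
whole-body protocol is 33 frames over 60 min: 10 x 15 s, 5 x 30 s,
5 x 60 s, 5 x 120 s and 8 x 300 s.
"""

from __future__ import annotations

import numpy as np

from .errors import ScheduleError

__all__ = ["FrameSchedule", "standard_33frame_schedule"]


class FrameSchedule:
    """Ordered, non-overlapping frame timing in seconds post-injection.

    Parameters
    ----------
    starts : array-like
        Frame start times in seconds, sorted ascending.
    durations : array-like
        Frame durations in seconds, all strictly positive.

    Notes
    -----
    Frames may leave gaps (interrupted protocols) but must not overlap:
    ``starts[i+1] >= starts[i] + durations[i]``.
    """

    def __init__(self, starts, durations):
        starts = np.asarray(starts, dtype=float)
        durations = np.asarray(durations, dtype=float)
        if starts.ndim != 1 or durations.ndim != 1 or starts.size != durations.size:
            raise ScheduleError("starts and durations must be 1-D and equally long")
        if starts.size == 0:
            raise ScheduleError("schedule must contain at least one frame")
        if not np.all(np.isfinite(starts)) or not np.all(np.isfinite(durations)):
            raise ScheduleError("frame times must be finite")
        if np.any(durations <= 0):
            raise ScheduleError("all frame durations must be > 0")
        if np.any(starts[1:] < starts[:-1] + durations[:-1]):
            raise ScheduleError("frames must be sorted and non-overlapping")
        self.starts = starts
        self.durations = durations
        self.starts.setflags(write=False)
        self.durations.setflags(write=False)

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        """Frame end times in seconds."""
        return self.starts + self.durations

    @property
    def mids(self) -> np.ndarray:
        """Frame mid-times in seconds."""
        return self.starts + self.durations / 2.0

    @property
    def mids_min(self) -> np.ndarray:
        """Frame mid-times in minutes (the kinetic-analysis time axis)."""
        return self.mids / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations / 60.0

    @property
    def total_span(self) -> float:
        """Seconds from the first frame start to the last frame end."""
        return float(self.ends[-1] - self.starts[0])

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.durations, other.durations)
        )

    def __repr__(self) -> str:
        return (
            f"FrameSchedule(n_frames={self.n_frames}, "
            f"span={self.total_span:.0f}s)"
        )

    def subset(self, indices) -> "FrameSchedule":
        """Schedule restricted to the given frame indices (kept sorted)."""
        idx = np.asarray(indices, dtype=int)
        return FrameSchedule(self.starts[idx], self.durations[idx])


def standard_33frame_schedule() -> FrameSchedule:
    """The 60-min, 33-frame whole-body dynamic protocol.

    10 frames of 15 s, 5 of 30 s, 5 of 60 s, 5 of 120 s and 8 of 300 s,
    contiguous from injection, spanning 3600 s in total.
    """
    durations = np.array([15.0] * 10 + [30.0] * 5 + [60.0] * 5 + [120.0] * 5 + [300.0] * 8)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)
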