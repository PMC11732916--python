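"""Image-derived input function (IDIF) and the running plasma integral.

The arterial input is taken directly from the blood-pool VOI (descending
aorta in the whole-body protocol): the per-frame arithmetic mean over all
voxels of the label, used as plasma without a whole-blood/plasma ratio or
metabolite correction.  The cumulative plasma integral — the Patlak
abscissa numerator — is the trapezoidal integral of the piecewise-linear
curve through ``(0, 0)`` and the frame mid-time points, in SUV*min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import DynamicImage, VoiSet
from .errors import ExtractionError
from .schedule import FrameSchedule

__all__ = [
    "TimeActivityCurve",
    "InputFunction",
    "FengInput",
    "extract_idif",
    "cumulative_plasma_integral",
]


@dataclass
class TimeActivityCurve:
    """Per-frame mean activity (SUV) of one VOI or voxel."""

    values: np.ndarray
    schedule: FrameSchedule
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.schedule.n_frames:
            raise ExtractionError(
                f"TAC has {self.values.size} values for a "
                f"{self.schedule.n_frames}-frame schedule"
            )
        if not np.all(np.isfinite(self.values)):
            raise ExtractionError("TAC contains non-finite values")


@dataclass
class InputFunction:
    """Plasma TAC together with its cumulative integral at frame mid-times.

    ``integral[i]`` is the running integral of the plasma curve (anchored
    at the (0, 0) injection point) evaluated at ``schedule.mids_min[i]``,
    in SUV*min.
    """

    tac: TimeActivityCurve
    integral: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.integral is None:
            self.integral = cumulative_plasma_integral(self.tac)
        self.integral = np.asarray(self.integral, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.tac.values

    @property
    def schedule(self) -> FrameSchedule:
        return self.tac.schedule

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.schedule.mids_min,
                "suv": self.values,
                "cumulative_integral": self.integral,
            }
        )


class FengInput:
    """Parametric arterial input: tri-exponential with a linear rise.

    ``Cp(t) = (A1*(t-d) - A2 - A3) * exp(-l1*(t-d))
              + A2 * exp(-l2*(t-d)) + A3 * exp(-l3*(t-d))``  for ``t >= d``,
    and 0 before the delay ``d`` (all times in minutes, amplitudes in SUV).
    ``Cp(d) = 0`` by construction.

    The defaults produce a single bolus peak of ~19 SUV at ~45 s
    post-injection and a slow tail at ~15% of the peak by 60 min — the
    canonical shape of a whole-blood FDG curve sampled in a large vessel.
    The fast third exponential dies out within ~8 min so the late tail is
    effectively mono-exponential.
    """

    def __init__(
        self,
        A1: float = 57.6,
        A2: float = 4.46,
        A3: float = 13.68,
        l1: float = 1.5,
        l2: float = 0.008,
        l3: float = 0.95,
        delay: float = 0.0,
    ):
        self.A1, self.A2, self.A3 = float(A1), float(A2), float(A3)
        self.l1, self.l2, self.l3 = float(l1), float(l2), float(l3)
        self.delay = float(delay)

    def __call__(self, t_min) -> np.ndarray:
        """Evaluate Cp at time(s) ``t_min`` (minutes post-injection)."""
        t = np.asarray(t_min, dtype=float) - self.delay
        v = (
            (self.A1 * t - self.A2 - self.A3) * np.exp(-self.l1 * np.maximum(t, 0.0))
            + self.A2 * np.exp(-self.l2 * np.maximum(t, 0.0))
            + self.A3 * np.exp(-self.l3 * np.maximum(t, 0.0))
        )
        return np.where(t > 0, v, 0.0)

    def frame_averages(self, schedule: FrameSchedule, n_sub: int = 64) -> np.ndarray:
        """Frame-interval averages of Cp (composite trapezoid per frame)."""
        out = np.empty(schedule.n_frames)
        for i, (s, d) in enumerate(zip(schedule.starts, schedule.durations)):
            tt = np.linspace(s, s + d, n_sub + 1) / 60.0
            out[i] = np.trapezoid(self(tt), tt) / (d / 60.0)
        return out

    def parameters(self) -> dict:
        return {
            "A1": self.A1, "A2": self.A2, "A3": self.A3,
            "l1": self.l1, "l2": self.l2, "l3": self.l3, "delay": self.delay,
        }


def extract_idif(image: DynamicImage, vois: VoiSet, blood_label) -> TimeActivityCurve:
    """Mean TAC over all voxels of the blood-pool VOI.

    Plain arithmetic voxel mean per frame (no volume weighting across
    slices).  Raises :class:`ExtractionError` on an empty VOI.
    """
    mask = vois.mask(blood_label)
    if not mask.any():
        raise ExtractionError(f"blood-pool VOI {blood_label!r} is empty")
    name = (
        blood_label if isinstance(blood_label, str) else vois.names[int(blood_label)]
    )
    values = image.voxels[mask].mean(axis=0)
    return TimeActivityCurve(values, image.schedule, source=str(name))


def cumulative_plasma_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Running trapezoidal integral of a TAC at its frame mid-times.

    The curve is taken piecewise-linear through ``(0, 0)`` — the
    injection-time anchor — and the points ``(mid_i, value_i)``; the
    returned array holds the integral at each mid-time, in SUV*min.
    """
    mids = np.concatenate([[0.0], tac.schedule.mids_min])
    vals = np.concatenate([[0.0], tac.values])
    seg = 0.5 * (vals[1:] + vals[:-1]) * np.diff(mids)
    return np.cumsum(seg)
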