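"""Indirect Patlak graphical analysis: per-VOI and per-voxel influx maps.

For an irreversible tracer the transformed coordinates

    x_i = (int_0^t_i Cp) / Cp(t_i)   [min]
    y_i = CT(t_i) / Cp(t_i)          [unitless]

become linear once the reversible pools equilibrate; a weighted
least-squares line over a late window gives the net influx ``Ki``
(slope, 1/min in SUV units) and the distribution volume ``DV``
(intercept).  Two protocol presets are built in: the short window
(``sti``, the last six 300-s frames, 30 min of data) and the long window
(``lti``, every frame except the first three, 59.25 min).  Note that the
slope of the measured TAC converges to ``(1-vB)*K1*k3/(k2+k3)``: the
blood-volume fraction scales the tissue signal, and no attempt is made
to correct for it (``vB`` is unknown without a compartment fit).

Windows are selected by frame count exactly as acquired; the long preset
deliberately includes early, non-equilibrated frames — the resulting
slope shift for late-equilibrating tissue is a property of the protocol
choice, not an artifact to be repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import DynamicImage
from .errors import FitError, ParameterError, WindowError
from .input_function import InputFunction, TimeActivityCurve
from .kinetics import _resolve_weights
from .schedule import FrameSchedule

__all__ = [
    "CP_GUARD_EPS",
    "PatlakWindow",
    "sti_window",
    "lti_window",
    "tstar_window",
    "patlak_transform",
    "PatlakModel",
    "PatlakResults",
    "patlak_fit",
    "patlak_parametric_maps",
]

#: plasma values at or below this (SUV) are excluded from the transform
CP_GUARD_EPS = 1e-6


@dataclass(frozen=True)
class PatlakWindow:
    """Contiguous frame indices entering the line fit."""

    indices: tuple
    label: str = "custom"

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(idx) < 3:
            raise WindowError("a Patlak window needs at least 3 frames")
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise WindowError("window frames must be contiguous")
        if idx[0] < 0:
            raise WindowError("negative frame index")
        object.__setattr__(self, "indices", idx)

    def validate(self, schedule: FrameSchedule) -> "PatlakWindow":
        if self.indices[-1] >= schedule.n_frames:
            raise WindowError(
                f"window frame {self.indices[-1]} outside the "
                f"{schedule.n_frames}-frame schedule"
            )
        return self

    @property
    def slice(self) -> slice:
        return slice(self.indices[0], self.indices[-1] + 1)

    def span_seconds(self, schedule: FrameSchedule) -> float:
        """Seconds of data covered, first start to last end."""
        return float(
            schedule.ends[self.indices[-1]] - schedule.starts[self.indices[0]]
        )


def sti_window(schedule: FrameSchedule) -> PatlakWindow:
    """Short-time window: the last 6 frames (30 min on the standard protocol)."""
    n = schedule.n_frames
    if n < 6:
        raise WindowError(f"short-time window needs >= 6 frames, schedule has {n}")
    return PatlakWindow(tuple(range(n - 6, n)), label="STI")


def lti_window(schedule: FrameSchedule) -> PatlakWindow:
    """Long-time window: all frames except the first 3 (59.25 min)."""
    n = schedule.n_frames
    if n < 6:
        raise WindowError(f"long-time window needs >= 6 frames, schedule has {n}")
    return PatlakWindow(tuple(range(3, n)), label="LTI")


def tstar_window(schedule: FrameSchedule, tstar_min: float) -> PatlakWindow:
    """Window from the first frame whose mid-time is >= ``tstar_min``."""
    mids = schedule.mids_min
    first = int(np.searchsorted(mids, tstar_min))
    if schedule.n_frames - first < 3:
        raise WindowError(f"fewer than 3 frames at or beyond t* = {tstar_min} min")
    return PatlakWindow(tuple(range(first, schedule.n_frames)), label=f"t*={tstar_min:g}")


def resolve_window(window, schedule: FrameSchedule) -> PatlakWindow:
    """Accept a preset name (``sti``/``lti``), a t* float, or a window."""
    if isinstance(window, PatlakWindow):
        return window.validate(schedule)
    if isinstance(window, str):
        name = window.lower()
        if name == "sti":
            return sti_window(schedule)
        if name == "lti":
            return lti_window(schedule)
        raise WindowError(f"unknown window preset {window!r}")
    if isinstance(window, (int, float)):
        return tstar_window(schedule, float(window))
    raise WindowError(f"cannot interpret window {window!r}")


def patlak_transform(tissue: TimeActivityCurve, input_fn: InputFunction):
    """Patlak coordinates for every frame, with the plasma guard applied.

    Returns ``(x, y, valid)`` where ``valid`` flags frames with
    ``Cp > CP_GUARD_EPS``; excluded frames carry NaN coordinates.
    """
    if tissue.schedule != input_fn.schedule:
        raise ParameterError("tissue TAC and input function must share a schedule")
    cp = input_fn.values
    valid = cp > CP_GUARD_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(valid, input_fn.integral / cp, np.nan)
        y = np.where(valid, tissue.values / cp, np.nan)
    return x, y, valid


def _wls_line(x, y, w):
    """Weighted least-squares slope/intercept with standard errors."""
    w = w / w.sum()
    xb = float(w @ x)
    yb = float(w @ y)
    sxx = float(w @ ((x - xb) ** 2))
    if sxx == 0:
        raise FitError("degenerate Patlak abscissa (zero spread)")
    slope = float(w @ ((x - xb) * (y - yb))) / sxx
    intercept = yb - slope * xb
    resid = y - (slope * x + intercept)
    rss = float(w @ resid**2) * len(x)
    n = len(x)
    dof = max(n - 2, 1)
    s2 = rss / n / dof  # mean weighted square / dof, scaled like OLS below
    se_slope = np.sqrt(s2 * n / (n * sxx))
    se_intercept = np.sqrt(s2 * n * (1.0 / n + xb * xb / (n * sxx)))
    return slope, intercept, rss, se_slope, se_intercept


class PatlakResults:
    """Slope (net influx), intercept (distribution volume) and diagnostics."""

    def __init__(self, model, ki, dv, rss, n_used, se_ki, se_dv):
        self.model = model
        self.ki = float(ki)
        self.dv = float(dv)
        self.rss = float(rss)
        self.n_frames_used = int(n_used)
        self.bse = np.array([se_ki, se_dv])

    def summary(self) -> str:
        win = self.model.window
        lines = [
            "Patlak graphical analysis",
            "=" * 44,
            f"{'window':<22}{win.label:>12}",
            f"{'frames used':<22}{self.n_frames_used:>12d}",
            f"{'weights':<22}{self.model.weights_label:>12}",
            f"{'RSS':<22}{self.rss:>12.5g}",
            "-" * 44,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
            f"{'Ki':<8}{self.ki:>14.5g}{self.bse[0]:>14.3g}",
            f"{'DV':<8}{self.dv:>14.5g}{self.bse[1]:>14.3g}",
        ]
        return "\n".join(lines)


class PatlakModel:
    """Weighted linear model on the Patlak-transformed coordinates.

    Parameters
    ----------
    tac : TimeActivityCurve
    input_fn : InputFunction
    window : PatlakWindow, "sti", "lti" or float (t* in minutes)
    weights : None, "uniform", "duration" or per-frame array
    """

    def __init__(self, tac: TimeActivityCurve, input_fn: InputFunction,
                 window="lti", weights=None):
        self.tac = tac
        self.input_fn = input_fn
        self.window = resolve_window(window, tac.schedule)
        self.weights_label = weights if isinstance(weights, str) else (
            "uniform" if weights is None else "custom")
        self._weights = _resolve_weights(weights, tac.schedule)

    def fit(self) -> PatlakResults:
        x, y, valid = patlak_transform(self.tac, self.input_fn)
        idx = np.asarray(self.window.indices)
        usable = idx[valid[idx]]
        if usable.size < 3:
            raise FitError(
                f"only {usable.size} usable frames in window {self.window.label!r} "
                "after the plasma guard"
            )
        slope, intercept, rss, se_s, se_i = _wls_line(
            x[usable], y[usable], self._weights[usable]
        )
        return PatlakResults(self, slope, intercept, rss, usable.size, se_s, se_i)


def patlak_fit(tissue: TimeActivityCurve, input_fn: InputFunction,
               window="lti", weights=None) -> PatlakResults:
    """Convenience wrapper: fit the Patlak line for one VOI TAC."""
    return PatlakModel(tissue, input_fn, window=window, weights=weights).fit()


def patlak_parametric_maps(image: DynamicImage, input_fn: InputFunction,
                           window="lti", weights=None, mask=None):
    """Voxel-wise Patlak fit across the volume.

    Parameters
    ----------
    image : DynamicImage
    input_fn : InputFunction (shares the image schedule)
    window, weights : as for :class:`PatlakModel`
    mask : ndarray of bool, optional
        Voxels to fit; defaults to the whole grid.

    Returns
    -------
    (ki_map, dv_map, fitted) : 3-D float maps (NaN where not fitted) and
        the boolean mask of voxels that were fitted.

    Notes
    -----
    The plasma guard is frame-level (it depends only on Cp), so all
    voxels share the same usable frames and the weighted line fit is
    evaluated in closed form over the whole grid at once.  When fewer
    than 3 frames survive the guard the maps are all-NaN rather than
    raising, so one bad window never aborts a volume.
    """
    if image.schedule != input_fn.schedule:
        raise ParameterError("image and input function must share a schedule")
    win = resolve_window(window, image.schedule)
    w_all = _resolve_weights(weights, image.schedule)

    cp = input_fn.values
    idx = np.asarray(win.indices)
    usable = idx[cp[idx] > CP_GUARD_EPS]
    shape = image.spatial_shape
    ki = np.full(shape, np.nan)
    dv = np.full(shape, np.nan)
    if usable.size < 3:
        return ki, dv, np.zeros(shape, dtype=bool)

    if mask is None:
        mask = np.ones(shape, dtype=bool)
    x = input_fn.integral[usable] / cp[usable]
    w = w_all[usable]
    w = w / w.sum()
    vox = image.voxels[mask][:, usable]  # (n_vox, n_frames)
    y = vox / cp[usable]
    xb = float(w @ x)
    yb = y @ w
    dx = x - xb
    sxx = float(w @ dx**2)
    slope = ((y - yb[:, None]) * (w * dx)).sum(axis=1) / sxx
    intercept = yb - slope * xb
    ki[mask] = slope
    dv[mask] = intercept
    fitted = mask & np.isfinite(ki)
    return ki, dv, fitted
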