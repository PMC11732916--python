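"""Two-tissue compartment model: forward solution and weighted NLS fitting.

The model describes FDG exchange between plasma (``Cp``), a free/
transported tissue pool ``C1`` and a trapped phosphorylated pool ``C2``::

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

with the measured tissue concentration

    CT(t) = (1 - vB) * (C1(t) + C2(t)) + vB * Cp(t)

``vB`` is the fractional blood volume (unitless), ``K1`` the uptake rate
(mL/ccm/min), ``k2`` clearance, ``k3`` phosphorylation by hexokinase and
``k4`` dephosphorylation (all 1/min).  ``k4`` is fixed to zero by default
(irreversible model), matching the configuration under which the Patlak
net-influx comparison is meaningful.  The net influx constant is

    Ki = K1 * k3 / (k2 + k3).

The forward solution is analytic for a piecewise-linear input: each
compartment response is an exponential convolved with the input, and on a
uniform fine grid the per-step update is evaluated in closed form, so the
only discretisation error is the piecewise-linear representation of Cp
itself (continuous parametric inputs are sampled on the same grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import least_squares

from .errors import FitError, ParameterError
from .input_function import FengInput, InputFunction, TimeActivityCurve
from .schedule import FrameSchedule

__all__ = [
    "KineticParams",
    "influx_from_rates",
    "forward_2tcm",
    "FitSettings",
    "TwoTissueModel",
    "TwoTissueResults",
    "fit_2tcm",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of one tissue; also used as phantom ground truth."""

    vB: float
    K1: float
    k2: float
    k3: float
    k4: float = 0.0

    @property
    def ki(self) -> float:
        """Net influx constant ``K1*k3/(k2+k3)`` (0 when ``k2+k3 == 0``)."""
        if self.k2 + self.k3 <= 0:
            return 0.0
        return self.K1 * self.k3 / (self.k2 + self.k3)

    def as_dict(self) -> dict:
        return {
            "vB": self.vB, "K1": self.K1, "k2": self.k2,
            "k3": self.k3, "k4": self.k4, "Ki": self.ki,
        }

    def validate_ground_truth(self) -> "KineticParams":
        """Check the constraints a generating parameter set must satisfy."""
        if not 0.0 <= self.vB <= 1.0:
            raise ParameterError(f"vB must be in [0, 1], got {self.vB}")
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ParameterError("ground-truth rate constants must be >= 0")
        return self


def influx_from_rates(K1: float, k2: float, k3: float) -> float:
    """Net influx constant ``Ki = K1*k3/(k2+k3)`` in mL/ccm/min.

    Returns 0 with a warning for the degenerate case ``k2 + k3 == 0``.
    """
    if k2 + k3 == 0:
        warnings.warn("k2 + k3 == 0: influx constant undefined, returning 0", stacklevel=2)
        return 0.0
    return K1 * k3 / (k2 + k3)


# ---------------------------------------------------------------------------
# analytic forward solution on a uniform grid


def _exp_step_coeffs(beta: float, h: float):
    """Closed-form step kernels for the exponential convolution.

    For ``y(t) = int_0^t exp(-beta*(t-s)) f(s) ds`` with ``f`` linear on a
    step of length ``h``:  ``E1 = int_0^h exp(-beta*u) du``,
    ``E2 = int_0^h u * ... `` arranged so that the new contribution of the
    segment with offset ``c0`` and slope ``b`` is ``c0*E1 + b*E2`` and its
    time-integral over the step is ``c0*E2 + b*E3`` (plus the decay of the
    carried-in state).  Series expansions keep ``beta -> 0`` exact.
    """
    x = beta * h
    if abs(x) < 1e-6:
        # series in beta*h, exact limits at beta == 0
        E1 = h * (1 - x / 2 + x * x / 6)
        E2 = h * h * (0.5 - x / 3 + x * x / 8)
        E3 = h * h * h * (1.0 / 6 - x / 8 + x * x / 20)
        a = 1 - x + x * x / 2
    else:
        a = np.exp(-x)
        E1 = -np.expm1(-x) / beta
        E2 = (h - E1) / beta
        E3 = (h * h / 2 - E2) / beta
    return a, E1, E2, E3


def _exp_conv(beta: float, f: np.ndarray, h: float, want_integral: bool = False):
    """``y(t) = int_0^t exp(-beta*(t-s)) f(s) ds`` for piecewise-linear ``f``
    on a uniform grid of step ``h`` (minutes); exact per segment.

    Optionally also returns ``I(t) = int_0^t y`` (needed for the trapped
    compartment), likewise exact per segment.
    """
    a, E1, E2, E3 = _exp_step_coeffs(beta, h)
    c0 = f[:-1]
    b = (f[1:] - f[:-1]) / h
    g = np.concatenate([[0.0], c0 * E1 + b * E2])
    y = signal.lfilter([1.0], [1.0, -a], g)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("exponential convolution overflowed")
    if not want_integral:
        return y
    seg = y[:-1] * E1 + c0 * E2 + b * E3
    integral = np.concatenate([[0.0], np.cumsum(seg)])
    return y, integral


def _resolve_cp(input_fn, t_min: np.ndarray) -> np.ndarray:
    """Plasma values on the fine grid from any supported input description.

    Continuous models are evaluated directly; sampled curves are taken
    piecewise-linear through the (0, 0) anchor and their frame mid-times,
    held flat beyond the last mid-time.
    """
    if callable(input_fn):
        return np.asarray(input_fn(t_min), dtype=float)
    if isinstance(input_fn, InputFunction):
        tac = input_fn.tac
    elif isinstance(input_fn, TimeActivityCurve):
        tac = input_fn
    else:
        raise ParameterError(f"unsupported input-function type: {type(input_fn)!r}")
    xp = np.concatenate([[0.0], tac.schedule.mids_min])
    fp = np.concatenate([[0.0], tac.values])
    return np.interp(t_min, xp, fp)


def _frame_average(values: np.ndarray, t_min: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval."""
    running = np.concatenate([[0.0], np.cumsum(0.5 * (values[1:] + values[:-1]) * np.diff(t_min))])
    at = np.interp
    s = schedule.starts / 60.0
    e = schedule.ends / 60.0
    return (at(e, t_min, running) - at(s, t_min, running)) / (e - s)


def forward_2tcm(
    params: KineticParams,
    input_fn,
    schedule: FrameSchedule,
    dt_s: float = 0.5,
    frame_average: bool = True,
) -> TimeActivityCurve:
    """Tissue TAC predicted by the compartment model.

    Parameters
    ----------
    params : KineticParams
    input_fn : FengInput, InputFunction, TimeActivityCurve or callable
        The plasma curve; callables are evaluated on the internal grid
        (time in minutes).
    schedule : FrameSchedule
    dt_s : float
        Internal grid step in seconds.  The default (0.5 s) keeps the
        piecewise-linear representation of a bolus-shaped input accurate
        to ~1e-7 relative on frame averages.
    frame_average : bool
        Average the continuous model curve over each frame interval
        (matching how scanners bin counts); if False, sample at mid-times.

    Returns
    -------
    TimeActivityCurve
    """
    h = dt_s / 60.0
    t_end = schedule.ends[-1] / 60.0
    n = int(round(t_end / h))
    t = np.linspace(0.0, n * h, n + 1)
    cp = _resolve_cp(input_fn, t)

    vB, K1, k2, k3, k4 = params.vB, params.K1, params.k2, params.k3, params.k4
    if k4 == 0.0:
        beta = k2 + k3
        c1, int_c1 = _exp_conv(beta, cp, h, want_integral=True)
        c1 = K1 * c1
        c2 = k3 * K1 * int_c1
        tissue = c1 + c2
    else:
        s = k2 + k3 + k4
        disc = max(s * s - 4.0 * k2 * k4, 0.0)
        root = np.sqrt(disc)
        b1 = 0.5 * (s - root)
        b2 = 0.5 * (s + root)
        if b2 - b1 < 1e-12:
            b2 = b1 + 1e-12
        y1 = _exp_conv(b1, cp, h)
        y2 = _exp_conv(b2, cp, h)
        denom = b2 - b1
        tissue = (K1 / denom) * ((k3 + k4 - b1) * y1 + (b2 - k3 - k4) * y2)
    ct = (1.0 - vB) * tissue + vB * cp

    if frame_average:
        values = _frame_average(ct, t, schedule)
    else:
        values = np.interp(schedule.mids_min, t, ct)
    return TimeActivityCurve(values, schedule, source="2tcm-forward")


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitSettings:
    """Iterative-fit configuration mirroring the "first fit" convention:
    a single descent from fixed initial values, terminated by whichever
    comes first of the iteration cap or the relative chi-square tolerance,
    with no restarts and (in the default mode) no parameter restrictions.
    """

    max_iter: int = 200
    ftol: float = 1e-6
    init: KineticParams = field(
        default_factory=lambda: KineticParams(vB=0.05, K1=0.1, k2=0.1, k3=0.01, k4=0.0)
    )
    bounds_mode: str = "unrestricted"  # or "nonnegative"
    k4_mode: str = "fixed-zero"  # or "free"
    dt_s: float = 1.0

    def __post_init__(self):
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.ftol <= 0:
            raise ParameterError("ftol must be > 0")
        if self.bounds_mode not in ("unrestricted", "nonnegative"):
            raise ParameterError(f"unknown bounds_mode {self.bounds_mode!r}")
        if self.k4_mode not in ("fixed-zero", "free"):
            raise ParameterError(f"unknown k4_mode {self.k4_mode!r}")


class TwoTissueResults:
    """Estimates, uncertainties and diagnostics of one compartment fit."""

    def __init__(self, model, params, cost, nfev, termination, jac, weights):
        self.model = model
        self.params: KineticParams = params
        self.chisq = float(cost)  # weighted residual sum of squares
        self.iterations = int(nfev)
        self.termination = termination  # "max-iter" | "tolerance"
        self._jac = jac
        self._weights = weights

    @property
    def ki(self) -> float:
        return self.params.ki

    @property
    def param_names(self):
        names = ["vB", "K1", "k2", "k3"]
        if self.model.settings.k4_mode == "free":
            names.append("k4")
        return names

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors from the Gauss-Newton approximation."""
        J = self._jac
        n, p = J.shape
        dof = max(n - p, 1)
        s2 = self.chisq / dof
        cov = np.linalg.pinv(J.T @ J) * s2
        return np.sqrt(np.maximum(np.diag(cov), 0.0))

    @property
    def fittedvalues(self) -> np.ndarray:
        return forward_2tcm(
            self.params, self.model.input_fn, self.model.tac.schedule,
            dt_s=self.model.settings.dt_s,
        ).values

    @property
    def resid(self) -> np.ndarray:
        return self.model.tac.values - self.fittedvalues

    def summary(self) -> str:
        lines = [
            "Two-tissue compartment model fit",
            "=" * 44,
            f"{'frames':<22}{self.model.tac.schedule.n_frames:>12d}",
            f"{'k4 mode':<22}{self.model.settings.k4_mode:>12}",
            f"{'bounds':<22}{self.model.settings.bounds_mode:>12}",
            f"{'chi-square':<22}{self.chisq:>12.5g}",
            f"{'function evals':<22}{self.iterations:>12d}",
            f"{'termination':<22}{self.termination:>12}",
            "-" * 44,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        est = [self.params.vB, self.params.K1, self.params.k2, self.params.k3]
        if self.model.settings.k4_mode == "free":
            est.append(self.params.k4)
        for name, val, se in zip(self.param_names, est, self.bse):
            lines.append(f"{name:<8}{val:>14.5g}{se:>14.3g}")
        lines.append("-" * 44)
        lines.append(f"{'Ki = K1*k3/(k2+k3)':<22}{self.ki:>12.5g}")
        return "\n".join(lines)


class TwoTissueModel:
    """Weighted nonlinear least-squares compartment model for one TAC.

    Parameters
    ----------
    tac : TimeActivityCurve
        Measured tissue curve (SUV per frame).
    input_fn : InputFunction or FengInput or callable
        Plasma input driving the model.
    settings : FitSettings, optional
    weights : None, "uniform", "duration" or array
        Per-frame weights of the squared residuals.  ``"duration"``
        weights by frame length (a surrogate for count statistics).
    """

    def __init__(self, tac: TimeActivityCurve, input_fn, settings: FitSettings = None,
                 weights=None):
        self.tac = tac
        self.input_fn = input_fn
        self.settings = settings if settings is not None else FitSettings()
        self.weights = _resolve_weights(weights, tac.schedule)
        if isinstance(input_fn, (InputFunction, TimeActivityCurve)):
            other = input_fn.schedule
            if other != tac.schedule:
                raise ParameterError("TAC and input function must share a schedule")

    def _unpack(self, theta: np.ndarray) -> KineticParams:
        if self.settings.k4_mode == "free":
            vB, K1, k2, k3, k4 = theta
        else:
            vB, K1, k2, k3 = theta
            k4 = 0.0
        return KineticParams(vB=vB, K1=K1, k2=k2, k3=k3, k4=k4)

    def _residuals(self, theta: np.ndarray, sqrt_w: np.ndarray) -> np.ndarray:
        params = self._unpack(theta)
        pred = forward_2tcm(
            params, self.input_fn, self.tac.schedule, dt_s=self.settings.dt_s
        ).values
        return sqrt_w * (pred - self.tac.values)

    def fit(self) -> TwoTissueResults:
        st = self.settings
        theta0 = [st.init.vB, st.init.K1, st.init.k2, st.init.k3]
        if st.k4_mode == "free":
            theta0.append(st.init.k4)
        theta0 = np.asarray(theta0, dtype=float)
        sqrt_w = np.sqrt(self.weights)

        last_finite = {"theta": theta0, "cost": np.inf}

        def fun(theta):
            try:
                r = self._residuals(theta, sqrt_w)
            except FloatingPointError:
                raise FitError(
                    "objective became non-finite during iteration; "
                    f"last finite iterate: {self._unpack(last_finite['theta'])}"
                )
            if not np.all(np.isfinite(r)):
                raise FitError(
                    "objective became non-finite during iteration; "
                    f"last finite iterate: {self._unpack(last_finite['theta'])}"
                )
            cost = float(r @ r)
            if cost <= last_finite["cost"]:
                last_finite["theta"] = theta.copy()
                last_finite["cost"] = cost
            return r

        npar = theta0.size
        max_nfev = st.max_iter * (npar + 1)
        common = dict(ftol=st.ftol, xtol=1e-12, gtol=1e-12, max_nfev=max_nfev)
        if st.bounds_mode == "unrestricted":
            res = least_squares(fun, theta0, method="lm", **common)
        else:
            lower = np.zeros(npar)
            lower[0] = 0.0
            upper = np.full(npar, np.inf)
            upper[0] = 1.0
            res = least_squares(fun, np.maximum(theta0, lower), method="trf",
                                bounds=(lower, upper), **common)
        termination = "max-iter" if res.status == 0 else "tolerance"
        params = self._unpack(res.x)
        return TwoTissueResults(
            self, params, 2.0 * res.cost, res.nfev, termination, res.jac, self.weights
        )


def _resolve_weights(weights, schedule: FrameSchedule) -> np.ndarray:
    if weights is None or (isinstance(weights, str) and weights == "uniform"):
        return np.ones(schedule.n_frames)
    if isinstance(weights, str):
        if weights == "duration":
            return schedule.durations_min.copy()
        raise ParameterError(f"unknown weights preset {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (schedule.n_frames,) or np.any(w < 0):
        raise ParameterError("weights must be nonnegative, one per frame")
    return w


def fit_2tcm(tac: TimeActivityCurve, input_fn, settings: FitSettings = None,
             weights=None) -> TwoTissueResults:
    """Convenience wrapper: fit the compartment model to one TAC."""
    return TwoTissueModel(tac, input_fn, settings=settings, weights=weights).fit()
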