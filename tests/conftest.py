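import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import dynpet as dp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return dp.standard_33frame_schedule()


@pytest.fixture(scope="session")
def feng():
    return dp.FengInput()


@pytest.fixture(scope="session")
def library():
    return dp.default_tissue_library()


@pytest.fixture(scope="session")
def analytic_input(schedule, feng):
    """Noiseless input function built from the exact frame averages of the
    parametric plasma model (what a perfect IDIF would measure)."""
    tac = dp.TimeActivityCurve(feng.frame_averages(schedule), schedule, source="cp")
    return dp.InputFunction(tac)


@pytest.fixture(scope="session")
def small_noiseless_phantom():
    """Quarter-scale phantom without noise (shared across tests)."""
    spec = dp.default_phantom_spec(noise_scale=0.0, seed=0, grid_shape=(24, 24, 48))
    return dp.build_phantom(spec), spec


@pytest.fixture(scope="session")
def small_noisy_phantom():
    spec = dp.default_phantom_spec(noise_scale=0.3, seed=7, grid_shape=(24, 24, 48))
    return dp.build_phantom(spec), spec


@pytest.fixture(scope="session")
def ode_oracle(feng):
    """Stiff ODE integration of the compartment equations, frame-averaged.

    Independent of the package's analytic convolution path: uses
    scipy.solve_ivp (LSODA) on the continuous model and trapezoidal
    frame averaging on a fine grid.
    """
    from scipy.integrate import solve_ivp

    def solve(params, schedule, n_grid=144001, rtol=1e-11, atol=1e-13):
        t = np.linspace(0.0, schedule.ends[-1] / 60.0, n_grid)

        def rhs(tt, y):
            cp = float(feng(tt))
            c1, c2 = y
            return [
                params.K1 * cp - (params.k2 + params.k3) * c1 + params.k4 * c2,
                params.k3 * c1 - params.k4 * c2,
            ]

        sol = solve_ivp(rhs, (t[0], t[-1]), [0.0, 0.0], t_eval=t,
                        rtol=rtol, atol=atol, method="LSODA")
        ct = (1 - params.vB) * (sol.y[0] + sol.y[1]) + params.vB * feng(t)
        running = np.concatenate(
            [[0.0], np.cumsum(0.5 * (ct[1:] + ct[:-1]) * np.diff(t))]
        )
        s, e = schedule.starts / 60.0, schedule.ends / 60.0
        return (np.interp(e, t, running) - np.interp(s, t, running)) / (e - s)

    return solve
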