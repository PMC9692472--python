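import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def fine_step_two_site(times, kpl, t1p, t1l, rho=0.0, bolus="delta",
                       arrival=0.0, shape=3.0, scale=1.5, amplitude=1.0,
                       dt=0.005):
    """Independent fixed-step RK4 oracle for the driven two-site exchange.

    Deliberately shares no code with the package: explicit RK4 on a dense
    grid, linear interpolation to the sample times.
    """
    from scipy.stats import gamma

    a_p = 1.0 / t1p + kpl + rho
    a_l = 1.0 / t1l + rho
    t_grid = np.arange(0.0, times[-1] + dt, dt)

    if bolus == "delta":
        def u(t):
            return 0.0
    else:
        def u(t):
            return amplitude * gamma.pdf(t - arrival, a=shape, scale=scale)

    p = np.zeros_like(t_grid)
    l = np.zeros_like(t_grid)
    if bolus == "delta":
        start = np.searchsorted(t_grid, arrival)
        p[start] = amplitude
    else:
        start = 0

    def deriv(t, pv, lv):
        return u(t) - a_p * pv, kpl * pv - a_l * lv

    for i in range(start, len(t_grid) - 1):
        t = t_grid[i]
        k1p, k1l = deriv(t, p[i], l[i])
        k2p, k2l = deriv(t + dt / 2, p[i] + dt / 2 * k1p, l[i] + dt / 2 * k1l)
        k3p, k3l = deriv(t + dt / 2, p[i] + dt / 2 * k2p, l[i] + dt / 2 * k2l)
        k4p, k4l = deriv(t + dt, p[i] + dt * k3p, l[i] + dt * k3l)
        p[i + 1] = p[i] + dt / 6 * (k1p + 2 * k2p + 2 * k3p + k4p)
        l[i + 1] = l[i] + dt / 6 * (k1l + 2 * k2l + 2 * k3l + k4l)

    return np.interp(times, t_grid, p), np.interp(times, t_grid, l)
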