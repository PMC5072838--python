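import numpy as np
import pytest
from hypothesis import settings

from chemoscape.competition import CompetitionParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def default_baseline():
    """1:1 inoculum at 1/2000 of capacity, ancestral rate 1.0/h."""
    return CompetitionParams()


def fine_step_log_ratio(r_m, r_w, m0, w0, t, k=1.0, n_steps=400_000):
    """Independent fixed-grid RK4 integrator for the two-strain competition.

    Deliberately shares no code with the package's adaptive integrator; used
    as an oracle for terminal log ratios.
    """
    h = t / n_steps
    m, w = m0, w0

    def f(m, w):
        s = 1.0 - (m + w) / k
        return r_m * m * s, r_w * w * s

    for _ in range(n_steps):
        k1m, k1w = f(m, w)
        k2m, k2w = f(m + 0.5 * h * k1m, w + 0.5 * h * k1w)
        k3m, k3w = f(m + 0.5 * h * k2m, w + 0.5 * h * k2w)
        k4m, k4w = f(m + h * k3m, w + h * k3w)
        m += h * (k1m + 2 * k2m + 2 * k3m + k4m) / 6.0
        w += h * (k1w + 2 * k2w + 2 * k3w + k4w) / 6.0
    import math

    return math.log(m / w) - math.log(m0 / w0)


def ols_normal_equations(x, y, through_origin=False):
    """Closed-form OLS oracle via the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if through_origin:
        slope = float(x @ y) / float(x @ x)
        return 0.0, slope
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = float(x @ x), float(x @ y)
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return intercept, slope
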