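import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import leafheat as lh
from leafheat import datasets

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lab_env():
    """Constant 20 degC / 50% RH dark-lab environment over 10 minutes."""
    return lh.EnvironmentTrace.constant(
        T_air=293.15, RH_air=0.5, t_end=600.0
    )


@pytest.fixture(scope="session")
def plate_optics():
    return lh.OpticalProperties(alpha=0.98, epsilon=0.96)


@pytest.fixture(scope="session")
def aluminum_fixture():
    """Synthetic black aluminum plate run: 60 s pulse at 270 W/m2 + 9 min
    dark, 0.05 K sensor noise at 25 Hz."""
    return datasets.make_aluminum_fixture(seed=1)


@pytest.fixture(scope="session")
def leaf_fixture():
    """Synthetic leaf run: 10 s pulse at 270 W/m2 + 110 s dark."""
    return datasets.make_leaf_fixture(seed=11)


@pytest.fixture(scope="session")
def quick_mcmc():
    """Reduced sampler budget for tests that only need a rough posterior."""
    return lh.MCMCConfig(
        iterations=400, warmup=200, walkers_per_chain=6, seed=5
    )


def rk4_oracle(T0, t_grid, irradiance_of_t, T_air, RH, T_reflect, P_atm,
               alpha, epsilon, g_bh, g_sw, k, C_s=1010.0, lam=2.45e6):
    """Independent fixed-step RK4 integration of the energy balance.

    Deliberately re-derives the model from the flux formulas with plain
    Python floats (no scipy, no package code) so it can serve as the
    brute-force oracle for the production integrators.  ``irradiance_of_t``
    must be evaluated at segment-interior points only (the caller aligns
    the grid with the light switches).
    """
    import math

    theta = 5.670374419e-8
    R, M = 8.3145, 0.0289647
    rho_air = P_atm * M / (R * T_air)
    g_bw = g_bh / 0.92
    g_tot = 0.0 if (g_sw == 0 or g_bw == 0) else 1.0 / (1/g_sw + 1/g_bw)

    def es(T):
        tc = T - 273.15
        return 610.78 * math.exp(17.27 * tc / (tc + 237.3))

    ea = RH * es(T_air)

    def f(t, T, I):
        sw = alpha * I
        lw = 2 * epsilon * theta * (T_reflect**4 - T**4)
        h = 2 * rho_air * C_s * g_bh * (T - T_air)
        le = 2 * lam * (0.622 * rho_air / P_atm) * g_tot * (es(T) - ea)
        return (sw + lw - h - le) / k

    out = [T0]
    T = T0
    for i in range(len(t_grid) - 1):
        t0, t1 = t_grid[i], t_grid[i + 1]
        h = t1 - t0
        tm = 0.5 * (t0 + t1)
        I = irradiance_of_t(tm)  # interior point: unambiguous segment
        k1 = f(t0, T, I)
        k2 = f(t0 + h / 2, T + h * k1 / 2, I)
        k3 = f(t0 + h / 2, T + h * k2 / 2, I)
        k4 = f(t1, T + h * k3, I)
        T = T + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(T)
    return np.array(out)
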