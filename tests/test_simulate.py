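import numpy as np
import pytest

import leafheat as lh
from leafheat.simulate import fast_transient

from conftest import rk4_oracle


@pytest.fixture(scope="module")
def leaf_setup():
    protocol = lh.LightProtocol.pulse(10.0, 50.0, 270.0)
    env = lh.EnvironmentTrace.constant(T_air=293.15, RH_air=0.5, t_end=60.0)
    optics = lh.OpticalProperties(0.92, 0.97)
    cond = lh.Conductances(g_bh=0.01, g_sw=0.002)
    return protocol, env, optics, cond


class TestLightProtocol:
    def test_pulse_constructor_layout(self):
        p = lh.LightProtocol.pulse(10.0, 110.0, 270.0)
        assert p.t_start == 0.0 and p.t_end == 120.0
        assert p.irradiance_at(5.0) == 270.0
        assert p.irradiance_at(10.0) == 0.0  # right-continuous at the switch
        assert p.irradiance_at(60.0) == 0.0

    @pytest.mark.parametrize("segments", [
        ((0.0, 10.0, 270.0), (12.0, 20.0, 0.0)),  # gap
        ((0.0, 0.0, 270.0),),  # empty segment
        ((0.0, 10.0, -5.0),),  # negative irradiance
    ])
    def test_invalid_segments_rejected(self, segments):
        with pytest.raises(ValueError):
            lh.LightProtocol(segments)

    def test_scaled_multiplies_irradiance_only(self):
        p = lh.LightProtocol.pulse(10.0, 110.0, 270.0).scaled(1.1)
        assert p.irradiance_at(5.0) == pytest.approx(297.0)
        assert p.t_end == 120.0


class TestIntegrateTemperature:
    def test_dark_equilibrium_stays_constant(self, leaf_setup):
        _, env, optics, cond = leaf_setup
        dark = lh.LightProtocol(((0.0, 30.0, 0.0),))
        T0 = lh.equilibrium_temperature(env.state_at(0.0), optics, cond)
        trace = lh.integrate_temperature(T0, dark, env, optics, cond, k=900.0)
        assert np.ptp(trace.T) < 1e-6

    def test_matches_independent_rk4_oracle(self, leaf_setup):
        """Adaptive integrator vs brute-force fixed-step RK4 at dt = 1 ms."""
        protocol, env, optics, cond = leaf_setup
        T0 = 292.0
        trace = lh.integrate_temperature(T0, protocol, env, optics, cond, k=900.0)
        grid = np.round(np.arange(0.0, 60.0 + 1e-9, 0.001), 9)
        oracle = rk4_oracle(
            T0, grid, protocol.irradiance_at, 293.15, 0.5, 293.15, 101325.0,
            optics.alpha, optics.epsilon, cond.g_bh, cond.g_sw, 900.0,
        )
        on_trace = np.interp(trace.times, grid, oracle)
        assert np.max(np.abs(trace.T - on_trace)) < 1e-3

    def test_pulse_rises_then_decays_monotonically(self, aluminum_fixture):
        """Plate trace shape: monotone rise during the pulse, then monotone
        decay toward the dark steady state."""
        fx = aluminum_fixture
        clean = lh.integrate_temperature(
            fx.trace.T[0] * 0 + 293.15, fx.protocol, fx.env,
            fx.sample.optics, fx.truth.conductances, fx.truth.k,
            sample_rate_hz=1.0,
        )
        pulse = clean.T[clean.times <= 60.0]
        dark = clean.T[clean.times >= 60.0]
        assert np.all(np.diff(pulse) > 0)
        assert np.all(np.diff(dark) < 0)
        # exponential-like decay ends at the dark equilibrium
        Teq = lh.equilibrium_temperature(
            fx.env.state_at(600.0), fx.sample.optics, fx.truth.conductances
        )
        assert clean.T[-1] == pytest.approx(Teq, abs=0.02)

    def test_larger_k_gives_smaller_temperature_rise(self, leaf_setup):
        protocol, env, optics, cond = leaf_setup
        rises = []
        for k in (600.0, 900.0, 1400.0):
            tr = lh.integrate_temperature(293.0, protocol, env, optics, cond, k)
            rises.append(lh.heating_slope(tr, (0.0, 10.0)))
        assert rises[0] > rises[1] > rises[2]

    def test_fast_kernel_agrees_with_adaptive_path(self, leaf_setup):
        protocol, env, optics, cond = leaf_setup
        ref = lh.integrate_temperature(292.5, protocol, env, optics, cond, 900.0)
        fast = fast_transient(
            292.5, protocol, env, optics, cond, 900.0, ref.times, dt=0.1
        )
        assert np.max(np.abs(ref.T - fast)) < 1e-4


class TestSyntheticTransient:
    def _truth(self):
        return lh.EnergyBalanceParams(
            k=900.0, conductances=lh.Conductances(0.01, 0.002)
        )

    def test_zero_noise_reproduces_exact_model(self, leaf_setup):
        protocol, env, optics, _ = leaf_setup
        tr = lh.generate_synthetic_transient(
            self._truth(), protocol, env, optics, noise_sd=0.0, seed=1
        )
        T0 = lh.equilibrium_temperature(
            env.state_at(0.0), optics, self._truth().conductances
        )
        clean = lh.integrate_temperature(
            T0, protocol, env, optics, self._truth().conductances, 900.0
        )
        assert np.array_equal(tr.T, clean.T)

    def test_seed_reproducibility(self, leaf_setup):
        protocol, env, optics, _ = leaf_setup
        a = lh.generate_synthetic_transient(
            self._truth(), protocol, env, optics, noise_sd=0.05, seed=42
        )
        b = lh.generate_synthetic_transient(
            self._truth(), protocol, env, optics, noise_sd=0.05, seed=42
        )
        assert np.array_equal(a.T, b.T)

    def test_noise_level_matches_request(self, leaf_setup):
        protocol, env, optics, _ = leaf_setup
        noisy = lh.generate_synthetic_transient(
            self._truth(), protocol, env, optics, noise_sd=0.05, seed=3
        )
        clean = lh.generate_synthetic_transient(
            self._truth(), protocol, env, optics, noise_sd=0.0
        )
        resid_sd = np.std(noisy.T - clean.T)
        assert resid_sd == pytest.approx(0.05, rel=0.1)


class TestHeatingSlope:
    def test_constant_trace_zero(self):
        t = np.arange(0.0, 20.0, 0.2)
        tr = lh.ThermalTrace(t, np.full_like(t, 293.15), 5.0)
        assert lh.heating_slope(tr, (0.0, 10.0)) == 0.0

    def test_linear_ramp(self):
        t = np.arange(0.0, 20.0, 0.2)
        tr = lh.ThermalTrace(t, 293.15 + 0.1 * t, 5.0)
        assert lh.heating_slope(tr, (0.0, 10.0)) == pytest.approx(0.1)

    def test_max_rise_over_exposure_time(self):
        # a 3.38 K maximum rise over a 10 s pulse -> 0.338 K/s
        t = np.arange(0.0, 20.0, 0.04)
        T = 293.15 + 3.38 * np.minimum(t / 8.0, 1.0)  # peaks inside window
        tr = lh.ThermalTrace(t, T, 25.0)
        assert lh.heating_slope(tr, (0.0, 10.0)) == pytest.approx(0.338)

    def test_empty_window_rejected(self):
        t = np.arange(0.0, 20.0, 0.2)
        tr = lh.ThermalTrace(t, np.full_like(t, 293.15), 5.0)
        with pytest.raises(ValueError):
            lh.heating_slope(tr, (30.0, 40.0))


class TestSplineDerivative:
    def test_straight_line_recovers_slope(self):
        t = np.linspace(0.0, 10.0, 100)
        tr = lh.ThermalTrace(t, 290.0 + 0.25 * t, 10.0)
        d = lh.spline_derivative(tr)
        assert np.allclose(d.T, 0.25, atol=1e-6)

    def test_matches_rhs_along_noiseless_trajectory(self, leaf_setup):
        protocol, env, optics, cond = leaf_setup
        T0 = lh.equilibrium_temperature(env.state_at(0.0), optics, cond)
        clean = lh.integrate_temperature(T0, protocol, env, optics, cond, 900.0)
        d = lh.spline_derivative(clean)
        expected = np.array([
            lh.energy_balance_rhs(
                T, env.state_at(t, I_s=protocol.irradiance_at(t)),
                optics, cond, 900.0,
            )
            for t, T in zip(clean.times, clean.T)
        ])
        # exclude +-1 s around the light switch where the spline smooths
        # over the slope discontinuity
        away = np.abs(clean.times - 10.0) > 1.0
        away &= (clean.times > 0.5) & (clean.times < 59.5)
        assert np.max(np.abs(d.T[away] - expected[away])) < 5e-3

    def test_smoothing_beats_raw_differencing_under_noise(self, leaf_setup):
        protocol, env, optics, cond = leaf_setup
        T0 = lh.equilibrium_temperature(env.state_at(0.0), optics, cond)
        clean = lh.integrate_temperature(T0, protocol, env, optics, cond, 900.0)
        rng = np.random.default_rng(4)
        noisy = lh.ThermalTrace(
            clean.times, clean.T + rng.normal(0, 0.05, len(clean)), 25.0
        )
        truth = np.gradient(clean.T, clean.times)
        spline_rmse = np.sqrt(np.mean(
            (lh.spline_derivative(noisy).T - truth) ** 2
        ))
        fd_rmse = np.sqrt(np.mean(
            (np.gradient(noisy.T, noisy.times) - truth) ** 2
        ))
        assert spline_rmse < fd_rmse

    def test_too_few_points_rejected(self):
        tr = lh.ThermalTrace(np.arange(5.0), 293.0 + np.arange(5.0), 1.0)
        with pytest.raises(ValueError):
            lh.spline_derivative(tr)


class TestDetectLightOnset:
    def _tape_trace(self, t_on=5.0):
        # fast-responding black tape: sharp exponential rise at t_on
        t = np.arange(0.0, 30.0, 0.04)
        T = 293.15 + np.where(
            t < t_on, 0.0, 2.0 * (1 - np.exp(-(t - t_on) / 1.5))
        )
        rng = np.random.default_rng(9)
        return lh.ThermalTrace(t, T + rng.normal(0, 0.02, t.size), 25.0)

    def test_recovers_known_onset(self):
        tr = self._tape_trace(t_on=5.0)
        assert lh.detect_light_onset(tr, threshold=0.3) == pytest.approx(
            5.0, abs=0.2
        )

    def test_constant_trace_raises(self):
        t = np.arange(0.0, 30.0, 0.04)
        tr = lh.ThermalTrace(t, np.full_like(t, 293.15), 25.0)
        with pytest.raises(RuntimeError):
            lh.detect_light_onset(tr, threshold=0.3)

    def test_zero_threshold_on_rising_trace_fires_immediately(self):
        t = np.arange(0.0, 30.0, 0.04)
        tr = lh.ThermalTrace(t, 293.15 + 0.1 * t, 25.0)
        assert lh.detect_light_onset(tr, threshold=0.0) == tr.times[0]


class TestThermalTrace:
    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            lh.ThermalTrace(np.array([0.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_decimate_keeps_every_nth(self):
        t = np.arange(0.0, 10.0, 0.04)
        tr = lh.ThermalTrace(t, 293.0 + t, 25.0)
        d = tr.decimate(5.0)
        assert d.sample_rate_hz == pytest.approx(5.0)
        assert np.allclose(np.diff(d.times), 0.2)
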