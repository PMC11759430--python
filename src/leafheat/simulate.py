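"""Forward simulation of temperature transients and trace-level estimators.

A measurement run exposes the sample to a light protocol — here typically a
short pulse (10 s for leaves, 60 s for the high-inertia aluminum plate) at
270 W m⁻² followed by darkness — while a thermal camera samples the object
temperature at 25 Hz.  This module integrates the energy-balance ODE under
such protocols, generates noisy synthetic observations, and provides the
estimators that operate directly on a trace: the heating slope during the
pulse, the smoothing-spline temperature derivative, and light-onset
detection from a reference (black tape) trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import make_smoothing_spline

from . import physics
from ._kernels import rk4_transient
from .constants import CP_AIR, LATENT_HEAT_VAPORIZATION

__all__ = [
    "LightProtocol",
    "EnvironmentTrace",
    "ThermalTrace",
    "integrate_temperature",
    "generate_synthetic_transient",
    "heating_slope",
    "spline_derivative",
    "detect_light_onset",
]


@dataclass(frozen=True)
class LightProtocol:
    """Ordered, contiguous irradiance segments (t_start, t_end, I_s).

    ``ppfd`` optionally records the photosynthetic photon flux densities of
    the segments (µmol m⁻² s⁻¹); it is metadata only and does not enter the
    energy balance.
    """

    segments: tuple[tuple[float, float, float], ...]
    ppfd: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        prev_end = None
        for t0, t1, I_s in self.segments:
            if t0 >= t1:
                raise ValueError(f"segment ({t0}, {t1}) has t_start >= t_end")
            if I_s < 0:
                raise ValueError("irradiance must be nonnegative")
            if prev_end is not None and not np.isclose(t0, prev_end):
                raise ValueError("segments must be contiguous and ordered")
            prev_end = t1

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def irradiance_at(self, t: float) -> float:
        """I_s at time t; right-continuous at segment edges, 0 outside."""
        for t0, t1, I_s in self.segments:
            if t0 <= t < t1:
                return I_s
        if t == self.t_end:
            return self.segments[-1][2]
        return 0.0

    def scaled(self, factor: float) -> "LightProtocol":
        """Protocol with every segment irradiance multiplied by ``factor``."""
        return LightProtocol(
            tuple((t0, t1, I_s * factor) for t0, t1, I_s in self.segments),
            ppfd=self.ppfd,
        )

    @classmethod
    def pulse(
        cls,
        pulse_duration: float = 10.0,
        dark_duration: float = 110.0,
        irradiance: float = 270.0,
        ppfd: float | None = 1250.0,
    ) -> "LightProtocol":
        """The standard pulse-then-dark protocol starting at t = 0."""
        return cls(
            ((0.0, pulse_duration, irradiance),
             (pulse_duration, pulse_duration + dark_duration, 0.0)),
            ppfd=(ppfd, 0.0) if ppfd is not None else None,
        )


@dataclass(frozen=True)
class EnvironmentTrace:
    """Time series of the atmospheric drivers (T_air/RH sensors log at 5 s).

    Values are interpolated piecewise-linearly inside the recorded range and
    held constant beyond its ends.
    """

    times: np.ndarray
    T_air: np.ndarray
    RH_air: np.ndarray
    T_reflect: np.ndarray
    P_atm: float = 101325.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("times must be a nonempty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("T_air", "RH_air", "T_reflect"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match times in shape")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "times", t)
        if self.P_atm <= 0:
            raise ValueError("P_atm must be positive")

    @classmethod
    def constant(
        cls,
        T_air: float,
        RH_air: float,
        T_reflect: float | None = None,
        P_atm: float = 101325.0,
        t_start: float = 0.0,
        t_end: float = 120.0,
        cadence: float = 5.0,
    ) -> "EnvironmentTrace":
        """Constant conditions sampled at the sensor cadence (default 5 s)."""
        if T_reflect is None:
            T_reflect = T_air
        t = np.arange(t_start, t_end + cadence, cadence)
        ones = np.ones_like(t)
        return cls(t, T_air * ones, RH_air * ones, T_reflect * ones, P_atm)

    def state_at(self, t: float, I_s: float = 0.0) -> physics.EnvironmentState:
        return physics.EnvironmentState(
            T_air=float(np.interp(t, self.times, self.T_air)),
            RH_air=float(np.interp(t, self.times, self.RH_air)),
            T_reflect=float(np.interp(t, self.times, self.T_reflect)),
            P_atm=self.P_atm,
            I_s=I_s,
        )

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.times, self.T_air, self.RH_air, self.T_reflect


@dataclass(frozen=True)
class ThermalTrace:
    """Sampled object temperature versus time (K), the observable."""

    times: np.ndarray
    T: np.ndarray
    sample_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        T = np.asarray(self.T, dtype=float)
        if t.ndim != 1 or t.shape != T.shape or len(t) < 2:
            raise ValueError("times and T must be matching 1-D arrays (n >= 2)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(T)):
            raise ValueError("temperatures must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "T", T)

    def __len__(self) -> int:
        return len(self.times)

    def decimate(self, target_rate_hz: float) -> "ThermalTrace":
        """Keep every n-th sample to approximate ``target_rate_hz``."""
        if target_rate_hz <= 0:
            raise ValueError("target rate must be positive")
        step = max(1, int(round(self.sample_rate_hz / target_rate_hz)))
        return ThermalTrace(
            self.times[::step], self.T[::step],
            sample_rate_hz=self.sample_rate_hz / step,
        )


def _protocol_arrays(protocol: LightProtocol) -> tuple[np.ndarray, np.ndarray]:
    bounds = np.array(
        [protocol.segments[0][0]] + [s[1] for s in protocol.segments]
    )
    irr = np.array([s[2] for s in protocol.segments])
    return bounds, irr


def integrate_temperature(
    T0: float,
    protocol: LightProtocol,
    env: EnvironmentTrace,
    optics: physics.OpticalProperties,
    cond: physics.Conductances,
    k: float,
    sample_rate_hz: float = 25.0,
    C_s: float = CP_AIR,
    lam: float = LATENT_HEAT_VAPORIZATION,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> ThermalTrace:
    """Reference forward solve of dT/dt = energy_balance_rhs under a protocol.

    Uses an adaptive Runge–Kutta (scipy RK45) restarted at every segment
    boundary so the step-size controller never straddles a discontinuity in
    I_s.  Output is sampled on a uniform grid at ``sample_rate_hz``.
    """
    if not np.isfinite(T0):
        raise ValueError("T0 must be finite")
    if k <= 0:
        raise ValueError("k must be positive")

    dt_out = 1.0 / sample_rate_hz
    out_times = np.arange(protocol.t_start, protocol.t_end + 0.5 * dt_out, dt_out)
    out_T = np.empty_like(out_times)
    out_T[0] = T0

    env_t, env_Tair, env_RH, env_Trefl = env.as_arrays()

    def rhs(t: float, y: np.ndarray, I_s: float) -> list[float]:
        state = physics.EnvironmentState(
            T_air=float(np.interp(t, env_t, env_Tair)),
            RH_air=float(np.interp(t, env_t, env_RH)),
            T_reflect=float(np.interp(t, env_t, env_Trefl)),
            P_atm=env.P_atm,
            I_s=I_s,
        )
        return [physics.energy_balance_rhs(
            float(y[0]), state, optics, cond, k, C_s=C_s, lam=lam
        )]

    T_current = T0
    for t0, t1, I_s in protocol.segments:
        mask = (out_times > t0) & (out_times <= t1)
        # always evaluate at t1 so the next segment restarts exactly there
        t_eval = np.unique(np.append(out_times[mask], t1))
        sol = solve_ivp(
            rhs, (t0, t1), [T_current], t_eval=t_eval,
            args=(I_s,), method="RK45", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed on segment ({t0}, {t1}) at I_s={I_s}: "
                f"{sol.message}"
            )
        out_T[mask] = sol.y[0][: int(mask.sum())]
        T_current = float(sol.y[0, -1])

    return ThermalTrace(out_times, out_T, sample_rate_hz=sample_rate_hz)


def fast_transient(
    T0: float,
    protocol: LightProtocol,
    env: EnvironmentTrace,
    optics: physics.OpticalProperties,
    cond: physics.Conductances,
    k: float,
    eval_times: np.ndarray,
    dt: float = 0.02,
    C_s: float = CP_AIR,
    lam: float = LATENT_HEAT_VAPORIZATION,
) -> np.ndarray:
    """Compiled fixed-step forward solve evaluated at ``eval_times``.

    This is the inner-loop solver used by the likelihood; it agrees with
    :func:`integrate_temperature` to well below sensor noise (see tests).
    """
    bounds, irr = _protocol_arrays(protocol)
    times, temps = rk4_transient(
        T0, bounds, irr, dt, *env.as_arrays(), env.P_atm,
        optics.alpha, optics.epsilon, cond.g_bh, cond.g_sw, k, C_s, lam,
    )
    return np.interp(eval_times, times, temps)


def generate_synthetic_transient(
    truth: physics.EnergyBalanceParams,
    protocol: LightProtocol,
    env: EnvironmentTrace,
    optics: physics.OpticalProperties,
    noise_sd: float = 0.05,
    seed: int | None = None,
    T0: float | None = None,
    sample_rate_hz: float = 25.0,
    C_s: float = CP_AIR,
    lam: float = LATENT_HEAT_VAPORIZATION,
) -> ThermalTrace:
    """Noisy synthetic observation of a transient with known parameters.

    Emulates the camera: the exact model trajectory plus i.i.d. zero-mean
    Gaussian sensor noise.  The default noise_sd of 0.05 K sits between the
    camera noise floor (NETD < 30 mK) and typical thermocouple noise
    (~0.2 K).  When ``T0`` is omitted the sample starts at its dark
    equilibrium temperature, emulating dark adaptation before the pulse.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if T0 is None:
        dark = env.state_at(protocol.t_start, I_s=0.0)
        T0 = physics.equilibrium_temperature(
            dark, optics, truth.conductances, C_s=C_s, lam=lam
        )
    clean = integrate_temperature(
        T0, protocol, env, optics, truth.conductances, truth.k,
        sample_rate_hz=sample_rate_hz, C_s=C_s, lam=lam,
    )
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = clean.T + rng.normal(0.0, noise_sd, size=len(clean))
    return ThermalTrace(clean.times, noisy, sample_rate_hz=sample_rate_hz)


def heating_slope(trace: ThermalTrace, pulse: tuple[float, float]) -> float:
    """Temperature response rate during the pulse (K s⁻¹).

    Defined as the maximum temperature rise within the pulse window over the
    exposure time: (max T in [t_on, t_off] − T(t_on)) / (t_off − t_on).
    """
    t_on, t_off = pulse
    if t_off <= t_on:
        raise ValueError("pulse window must have t_on < t_off")
    mask = (trace.times >= t_on) & (trace.times <= t_off)
    if not np.any(mask):
        raise ValueError("pulse window contains no samples")
    T_on = float(np.interp(t_on, trace.times, trace.T))
    return (float(trace.T[mask].max()) - T_on) / (t_off - t_on)


def spline_derivative(
    trace: ThermalTrace, smoothing: float | None = None
) -> ThermalTrace:
    """dT/dt estimated from a smoothing spline fit to the trace (K s⁻¹).

    A cubic smoothing spline is fit to T(t) and differentiated analytically;
    with ``smoothing=None`` the penalty is chosen by generalized
    cross-validation.  Returns a trace whose ``T`` field holds the
    derivative at the original sample times.
    """
    if len(trace) < 10:
        raise ValueError("need at least 10 samples for a smoothing spline")
    spl = make_smoothing_spline(trace.times, trace.T, lam=smoothing)
    deriv = spl.derivative()(trace.times)
    return ThermalTrace(trace.times, deriv, sample_rate_hz=trace.sample_rate_hz)


def detect_light_onset(
    reference_trace: ThermalTrace,
    threshold: float = 0.05,
    smoothing: float | None = None,
) -> float:
    """Light turn-on time from a fast-responding reference (black tape) trace.

    Returns the earliest sample time at which the smoothed temperature
    derivative exceeds ``threshold`` (K s⁻¹); used to align the protocol
    clock with the camera clock.
    """
    deriv = spline_derivative(reference_trace, smoothing=smoothing)
    above = deriv.T > threshold
    if not np.any(above):
        raise RuntimeError(
            f"derivative never exceeds threshold {threshold} K/s; "
            "no light onset detected"
        )
    return float(deriv.times[np.argmax(above)])
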