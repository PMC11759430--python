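"""Bayesian inversion of a thermal transient for (k, g_bh, g_sw) and C_p.

The observed temperature trace during and after a light pulse is compared
against the integrated energy-balance model; the areal heat capacity k, the
boundary-layer conductance g_bh, the stomatal conductance g_sw and the
residual noise sd σ are sampled jointly from

    p(k, g_bh, g_sw, σ | T_obs) ∝ N(T_obs | T_model(k, g_bh, g_sw), σ²) ·
                                  p(k) p(g_bh) p(g_sw) p(σ)

with half-normal priors restricted to the physically admissible nonnegative
half-line.  g_sw and g_bh carry the weak half-normal(0, 0.005 m s⁻¹)
priors of the measurement protocol; priors for k and σ are broad.  Sampling
uses an affine-invariant ensemble (emcee); walker groups play the role of
chains in the rank-normalized split-R̂/ESS convergence diagnostics, with
the conventional thresholds R̂ < 1.01 and ESS > 200.

The specific heat capacity follows per posterior draw as C_p = k / (ρ·lt),
where ρ·lt — fresh mass per unit area — is simply fresh weight over area,
so its credible interval inherits the full posterior uncertainty of k.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
from scipy.interpolate import make_smoothing_spline

from . import physics
from .constants import CP_AIR, LATENT_HEAT_VAPORIZATION
from ._kernels import rk4_env_grid
from .simulate import EnvironmentTrace, LightProtocol, ThermalTrace, heating_slope

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "FitResult",
    "log_posterior",
    "fit_transient",
    "derive_cp",
    "fit_rmse",
    "convergence_diagnostics",
]


@dataclass(frozen=True)
class PriorSpec:
    """Half-normal prior scales (all supports are the nonnegative half-line).

    ``g_sw_sd`` and ``g_bh_sd`` default to the protocol's weakly-informative
    0.005 m s⁻¹.  ``k_sd`` = 5000 J m⁻² K⁻¹ covers metal plates (~3000) and
    the full leaf range without being informative; ``sigma_sd`` = 0.5 K is
    broad relative to camera noise.
    """

    g_sw_sd: float = 0.005
    g_bh_sd: float = 0.005
    k_sd: float = 5000.0
    sigma_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("g_sw_sd", "g_bh_sd", "k_sd", "sigma_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler budget: 4 walker-groups × ``iterations`` steps, first
    ``warmup`` discarded.  ``walkers_per_chain`` sets the ensemble width."""

    chains: int = 4
    iterations: int = 1000
    warmup: int = 500
    seed: int = 0
    walkers_per_chain: int = 12
    solver_dt: float = 0.1  # inner RK4 step (s); « any thermal time constant

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for diagnostics")


@dataclass
class FitResult:
    """Posterior summary of a transient fit.

    ``draws`` maps parameter name → array of shape (chains, draws); the
    scalar summaries are posterior means and 95% equal-tailed credible
    intervals.  ``converged`` is False whenever any R̂ ≥ 1.01 or ESS ≤ 200.
    """

    draws: dict[str, np.ndarray]
    mean: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    rmse: float
    seed: int
    config: dict = field(default_factory=dict)
    predicted: ThermalTrace | None = None

    def summary_dict(self) -> dict:
        return {
            "parameters": {
                name: {
                    "mean": self.mean[name],
                    "ci95": [self.ci_low[name], self.ci_high[name]],
                    "rhat": self.rhat[name],
                    "ess": self.ess[name],
                }
                for name in self.mean
            },
            "converged": self.converged,
            "rmse_K": self.rmse,
            "seed": self.seed,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary_dict(), indent=2, **kwargs)


class _TransientModel:
    """Precomputed forward-solve context shared by all likelihood calls.

    Builds the fixed RK4 grid over the protocol, pre-interpolates the
    environment drivers at every node and half-node, and smooths the first
    observations into the initial temperature T0.
    """

    def __init__(
        self,
        trace: ThermalTrace,
        protocol: LightProtocol,
        env: EnvironmentTrace,
        optics: physics.OpticalProperties,
        dt: float = 0.1,
        C_s: float = CP_AIR,
        lam: float = LATENT_HEAT_VAPORIZATION,
        T0: float | None = None,
    ) -> None:
        self.obs_times = trace.times
        self.obs_T = trace.T
        self.optics = optics
        self.P_atm = env.P_atm
        self.C_s = C_s
        self.lam = lam

        seg_n, seg_h, node_times = [], [], [protocol.t_start]
        for t0, t1, _ in protocol.segments:
            n = max(1, int(math.ceil((t1 - t0) / dt)))
            h = (t1 - t0) / n
            seg_n.append(n)
            seg_h.append(h)
            node_times.extend(t0 + h * (i + 1) for i in range(n))
        self.seg_n = np.array(seg_n, dtype=np.int64)
        self.seg_h = np.array(seg_h)
        self.seg_irr = np.array([s[2] for s in protocol.segments])
        self.node_times = np.array(node_times)
        # node + half-node grid: index 2j = node j, 2j+1 = half-step after j
        half = 0.5 * (self.node_times[:-1] + self.node_times[1:])
        fine = np.empty(2 * len(self.node_times) - 1)
        fine[0::2] = self.node_times
        fine[1::2] = half
        et, eT, eRH, eTr = env.as_arrays()
        self.env_Tair = np.interp(fine, et, eT)
        self.env_RH = np.interp(fine, et, eRH)
        self.env_Trefl = np.interp(fine, et, eTr)

        if T0 is None:
            # smooth the noisy trace rather than trusting the first sample
            spl = make_smoothing_spline(trace.times, trace.T)
            T0 = float(spl(trace.times[0]))
        self.T0 = T0

    def predict(
        self, k: float, g_bh: float, g_sw: float, dT0: float = 0.0
    ) -> np.ndarray:
        """Model temperature at the observation times."""
        temps = rk4_env_grid(
            self.T0 + dT0, self.seg_n, self.seg_h, self.seg_irr,
            self.env_Tair, self.env_RH, self.env_Trefl, self.P_atm,
            self.optics.alpha, self.optics.epsilon,
            g_bh, g_sw, k, self.C_s, self.lam,
        )
        return np.interp(self.obs_times, self.node_times, temps)

    def irradiance_scaled(self, factor: float) -> "_TransientModel":
        import copy

        clone = copy.copy(self)
        clone.seg_irr = self.seg_irr * factor
        return clone


def _half_normal_logpdf(x: float, sd: float) -> float:
    if x < 0:
        return -np.inf
    return -0.5 * (x / sd) ** 2 - math.log(sd) + 0.5 * math.log(2.0 / math.pi)


def log_posterior(
    params: np.ndarray,
    model: _TransientModel,
    priors: PriorSpec,
    fix_g_sw: float | None = None,
    T0_prior_sd: float | None = None,
) -> float:
    """Log of the unnormalized posterior density.

    ``params`` is (k, g_bh, g_sw, σ), or (k, g_bh, σ) when ``fix_g_sw``
    pins the stomatal conductance (a dry plate has none).  When
    ``T0_prior_sd`` is given, one extra trailing element δT0 — the offset
    of the initial temperature from its smoothed-trace estimate, with a
    Normal(0, T0_prior_sd) prior — is appended, so the uncertainty of the
    starting temperature is marginalized rather than ignored.  Returns −∞
    outside the prior support and on forward-solve failure.
    """
    params = np.asarray(params, dtype=float)
    dT0 = 0.0
    lp_T0 = 0.0
    if T0_prior_sd is not None:
        dT0 = params[-1]
        params = params[:-1]
        lp_T0 = -0.5 * (dT0 / T0_prior_sd) ** 2
    if fix_g_sw is None:
        k, g_bh, g_sw, sigma = params
        lp_gsw = _half_normal_logpdf(g_sw, priors.g_sw_sd)
    else:
        k, g_bh, sigma = params
        g_sw = fix_g_sw
        lp_gsw = 0.0
    if k <= 0 or g_bh < 0 or g_sw < 0 or sigma <= 0:
        return -np.inf
    lp = (
        _half_normal_logpdf(k, priors.k_sd)
        + _half_normal_logpdf(g_bh, priors.g_bh_sd)
        + lp_gsw
        + _half_normal_logpdf(sigma, priors.sigma_sd)
        + lp_T0
    )
    try:
        pred = model.predict(k, g_bh, g_sw, dT0=dT0)
    except Exception as exc:  # pragma: no cover - solver pathology
        warnings.warn(f"forward solve failed at {params}: {exc}", stacklevel=2)
        return -np.inf
    if not np.all(np.isfinite(pred)):
        return -np.inf
    resid = model.obs_T - pred
    n = resid.size
    loglik = -0.5 * np.sum(resid**2) / sigma**2 - n * math.log(sigma) \
        - 0.5 * n * math.log(2.0 * math.pi)
    return lp + loglik


def _heuristic_init(
    trace: ThermalTrace,
    protocol: LightProtocol,
    env: EnvironmentTrace,
    optics: physics.OpticalProperties,
    C_s: float,
) -> tuple[float, float, float, float]:
    """Moment-style starting point: k from the onset slope αI/(dT/dt),
    g_bh from the post-pulse decay time constant, small g_sw, σ from the
    high-frequency jitter of the trace."""
    pulse_segs = [s for s in protocol.segments if s[2] > 0]
    t_on, t_off, I_s = pulse_segs[0] if pulse_segs else protocol.segments[0]
    try:
        slope = heating_slope(trace, (t_on, t_off))
    except ValueError:
        slope = 0.0
    k0 = optics.alpha * I_s / slope if slope > 1e-4 and I_s > 0 else 1000.0
    k0 = float(np.clip(k0, 50.0, 2e4))

    # decay time constant from peak to (1 - 1/e) of the way back down
    T_end = float(np.mean(trace.T[-max(3, len(trace) // 10):]))
    i_peak = int(np.argmax(trace.T))
    dT_peak = trace.T[i_peak] - T_end
    tau = 20.0
    if dT_peak > 0.2:
        target = T_end + dT_peak / math.e
        below = np.nonzero(trace.T[i_peak:] <= target)[0]
        if below.size:
            tau = max(1.0, float(trace.times[i_peak + below[0]] - trace.times[i_peak]))
    T_air = float(np.interp(t_on, env.times, env.T_air))
    rho_air = physics.air_density(T_air, env.P_atm)
    radiative = 8.0 * optics.epsilon * 5.670374419e-8 * T_air**3
    g_bh0 = max((k0 / tau - radiative) / (2.0 * rho_air * C_s), 5e-4)
    sigma0 = max(float(np.std(np.diff(trace.T)) / math.sqrt(2.0)), 1e-3)
    return k0, min(g_bh0, 0.05), 1e-3, sigma0


def _map_estimate(
    x0: np.ndarray,
    model: _TransientModel,
    priors: PriorSpec,
    fix_g_sw: float | None,
    T0_prior_sd: float | None,
) -> np.ndarray:
    """Posterior mode by Nelder–Mead, log-transforming the positive
    parameters (the trailing δT0, when present, stays on its natural scale).
    Returns the mode in the transformed (z) space.
    """
    from scipy.optimize import minimize

    n_pos = x0.size - (1 if T0_prior_sd is not None else 0)
    unpack = _make_unpack(n_pos)

    def neg_log_post(z: np.ndarray) -> float:
        lp = log_posterior(unpack(z), model, priors, fix_g_sw, T0_prior_sd)
        return -lp if np.isfinite(lp) else 1e12

    # conductances may legitimately start near 0; floor before taking logs
    z0 = np.concatenate([np.log(np.maximum(x0[:n_pos], 1e-8)), x0[n_pos:]])
    res = minimize(
        neg_log_post, z0, method="Nelder-Mead",
        options={"maxiter": 3000, "xatol": 1e-7, "fatol": 1e-9},
    )
    return res.x if np.isfinite(res.fun) else z0


def _make_unpack(n_pos: int):
    def unpack(z: np.ndarray) -> np.ndarray:
        x = np.empty_like(z)
        x[:n_pos] = np.exp(z[:n_pos])
        x[n_pos:] = z[n_pos:]
        return x

    return unpack


def _log_posterior_z(
    z: np.ndarray,
    n_pos: int,
    model: _TransientModel,
    priors: PriorSpec,
    fix_g_sw: float | None,
    T0_prior_sd: float | None,
) -> float:
    """Posterior density in log-transformed space, with the change-of-
    variables Jacobian Σ z_i for the log-transformed (positive) parameters.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z[:n_pos] > 50.0):  # e^50 is far outside any prior mass
        return -np.inf
    x = _make_unpack(n_pos)(z)
    lp = log_posterior(x, model, priors, fix_g_sw, T0_prior_sd)
    if not np.isfinite(lp):
        return -np.inf
    return lp + float(np.sum(z[:n_pos]))


def _laplace_chol(
    z_map: np.ndarray,
    n_pos: int,
    model: _TransientModel,
    priors: PriorSpec,
    fix_g_sw: float | None,
    T0_prior_sd: float | None,
    h: float = 1e-4,
) -> np.ndarray | None:
    """Cholesky factor of the Laplace-approximation covariance at the mode
    (z space); None when the numerical Hessian is not positive definite
    (flat or unidentified directions)."""
    d = z_map.size

    def f(z):
        lp = _log_posterior_z(z, n_pos, model, priors, fix_g_sw, T0_prior_sd)
        return -lp if np.isfinite(lp) else 1e12

    H = np.empty((d, d))
    f0 = f(z_map)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        fpp = f(z_map + ei)
        fmm = f(z_map - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            fij = f(z_map + ei + ej) - f(z_map + ei - ej) \
                - f(z_map - ei + ej) + f(z_map - ei - ej)
            H[i, j] = H[j, i] = fij / (4 * h**2)
    try:
        cov = np.linalg.inv(H)
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return None


def fit_transient(
    trace: ThermalTrace,
    protocol: LightProtocol,
    env: EnvironmentTrace,
    optics: physics.OpticalProperties,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    mass_per_area: float | None = None,
    fix_g_sw: float | None = None,
    decimate_to_hz: float | None = 5.0,
    C_s: float = CP_AIR,
    lam: float = LATENT_HEAT_VAPORIZATION,
    model: _TransientModel | None = None,
    estimate_T0: bool = True,
    T0_prior_sd: float = 0.2,
) -> FitResult:
    """Sample the posterior of (k, g_bh[, g_sw], σ) given an observed trace.

    Parameters
    ----------
    fix_g_sw : float, optional
        Pin the stomatal conductance (use ``0.0`` for a dry reference plate).
    decimate_to_hz : float, optional
        Observation rate used in the likelihood; 25 Hz camera traces are
        decimated to 5 Hz by default (the information loss is negligible
        because sensor noise is white and the dynamics are slow).
    mass_per_area : float, optional
        Fresh mass per unit area ρ·lt (kg m⁻²); when given, a ``C_p``
        posterior summary is added (C_p = k / mass_per_area per draw).
    model : optional
        Pre-built forward-solve context; used internally by the sensitivity
        analysis to refit with perturbed assumed inputs while holding the
        observed trace fixed.

    Notes
    -----
    The trace should span the pulse plus ≥ 30 s of the dark relaxation:
    the rise constrains k and the decay constrains the conductances.  A
    protocol with no light pulse leaves k unidentified; this is detected
    and warned about up front, and shows up as a prior-wide interval.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()

    if all(s[2] == 0 for s in protocol.segments):
        warnings.warn(
            "protocol contains no light pulse: k is not identifiable from "
            "an equilibrium trace", stacklevel=2,
        )
    dark_after = protocol.t_end - max(
        (s[1] for s in protocol.segments if s[2] > 0), default=protocol.t_start
    )
    if 0 < dark_after < 30.0:
        warnings.warn(
            f"only {dark_after:.0f} s of post-pulse darkness; conductance "
            "estimates may be poorly constrained", stacklevel=2,
        )

    fit_trace = trace
    if decimate_to_hz is not None and trace.sample_rate_hz > decimate_to_hz:
        fit_trace = trace.decimate(decimate_to_hz)

    if model is None:
        model = _TransientModel(
            fit_trace, protocol, env, optics,
            dt=mcmc.solver_dt, C_s=C_s, lam=lam,
        )

    k0, g_bh0, g_sw0, sigma0 = _heuristic_init(
        fit_trace, protocol, env, optics, C_s
    )
    if fix_g_sw is None:
        names = ["k", "g_bh", "g_sw", "sigma_obs"]
        x0 = np.array([k0, g_bh0, g_sw0, sigma0])
    else:
        names = ["k", "g_bh", "sigma_obs"]
        x0 = np.array([k0, g_bh0, sigma0])
    t0_sd = T0_prior_sd if estimate_T0 else None
    if estimate_T0:
        names = names + ["dT0"]
        x0 = np.append(x0, 0.0)
    ndim = len(x0)
    n_pos = ndim - (1 if estimate_T0 else 0)
    nwalkers = mcmc.chains * mcmc.walkers_per_chain

    # Sampling happens in log-transformed space (positivity built in, scale
    # parameters mix better); the Jacobian is applied in _log_posterior_z.
    # Warmup only has to explore the local posterior, not find it: the
    # moment-style start is refined to the mode, and walkers initialize
    # from the Laplace approximation there so the initial ensemble already
    # has the posterior's scale and orientation.
    z_map = _map_estimate(x0, model, priors, fix_g_sw, t0_sd)

    rng = np.random.default_rng(mcmc.seed)
    chol = _laplace_chol(z_map, n_pos, model, priors, fix_g_sw, t0_sd)
    if chol is None:
        # flat/unidentified directions: fall back to a generic 5% ball
        chol = np.diag(np.full(ndim, 0.05))
    p0 = z_map + rng.normal(size=(nwalkers, ndim)) @ chol.T

    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, _log_posterior_z,
        args=(n_pos, model, priors, fix_g_sw, t0_sd),
        moves=[
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ],
    )
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)
    ).get_state()
    # the Laplace-scaled ensemble can be extremely tight when the data are
    # nearly noiseless; emcee's condition-number heuristic would reject it
    sampler.run_mcmc(p0, mcmc.iterations, progress=False,
                     skip_initial_state_check=True)

    # (iterations, nwalkers, ndim) -> natural scale -> per-parameter
    # (chains, draws) with the walker axis split into `chains` groups
    chain = sampler.get_chain(discard=mcmc.warmup)
    chain[:, :, :n_pos] = np.exp(chain[:, :, :n_pos])
    n_draws = chain.shape[0]
    draws = {
        name: chain[:, :, i].T.reshape(mcmc.chains, mcmc.walkers_per_chain * n_draws)
        for i, name in enumerate(names)
    }

    diag = convergence_diagnostics(draws)
    converged = all(
        np.isfinite(diag["rhat"][n]) and diag["rhat"][n] < 1.01
        and diag["ess"][n] > 200.0
        for n in names
    )
    if not converged:
        warnings.warn(
            "MCMC did not meet convergence thresholds "
            f"(rhat={diag['rhat']}, ess={diag['ess']}); "
            "treat the posterior summaries with caution", stacklevel=2,
        )

    if mass_per_area is not None:
        draws["C_p"] = derive_cp(draws["k"], mass_per_area)
        diag["rhat"]["C_p"] = diag["rhat"]["k"]
        diag["ess"]["C_p"] = diag["ess"]["k"]

    mean = {n: float(np.mean(d)) for n, d in draws.items()}
    ci_low = {n: float(np.quantile(d, 0.025)) for n, d in draws.items()}
    ci_high = {n: float(np.quantile(d, 0.975)) for n, d in draws.items()}

    pred = model.predict(
        mean["k"], mean["g_bh"],
        mean["g_sw"] if fix_g_sw is None else fix_g_sw,
        dT0=mean.get("dT0", 0.0),
    )
    pred_trace = ThermalTrace(
        model.obs_times, pred, sample_rate_hz=fit_trace.sample_rate_hz
    )
    rmse = fit_rmse(fit_trace, pred_trace)

    return FitResult(
        draws=draws,
        mean=mean,
        ci_low=ci_low,
        ci_high=ci_high,
        rhat=diag["rhat"],
        ess=diag["ess"],
        converged=converged,
        rmse=rmse,
        seed=mcmc.seed,
        config={
            "chains": mcmc.chains,
            "iterations": mcmc.iterations,
            "warmup": mcmc.warmup,
            "walkers_per_chain": mcmc.walkers_per_chain,
            "solver_dt_s": mcmc.solver_dt,
            "decimate_to_hz": decimate_to_hz,
            "fix_g_sw": fix_g_sw,
            "estimate_T0": estimate_T0,
            "T0_prior_sd_K": T0_prior_sd,
            "mass_per_area_kg_m2": mass_per_area,
            "priors": {
                "k_sd": priors.k_sd, "g_bh_sd": priors.g_bh_sd,
                "g_sw_sd": priors.g_sw_sd, "sigma_sd": priors.sigma_sd,
            },
            "C_s": C_s, "lambda": lam, "P_atm": env.P_atm,
        },
        predicted=pred_trace,
    )


def derive_cp(k_draws: np.ndarray, mass_per_area: float) -> np.ndarray:
    """C_p draws (J kg⁻¹ K⁻¹) from k draws: per-draw division by ρ·lt.

    Because the transform is monotone, every posterior quantile of C_p is
    the corresponding quantile of k divided by ``mass_per_area``.
    """
    if mass_per_area <= 0:
        raise ValueError("mass_per_area must be positive")
    return np.asarray(k_draws, dtype=float) / mass_per_area


def fit_rmse(trace: ThermalTrace, predicted: ThermalTrace) -> float:
    """Root-mean-squared residual (K) between aligned observed/modelled traces."""
    if len(trace) != len(predicted) or not np.allclose(
        trace.times, predicted.times
    ):
        raise ValueError("traces must share the same time grid")
    return float(np.sqrt(np.mean((trace.T - predicted.T) ** 2)))


def convergence_diagnostics(
    draws: dict[str, np.ndarray] | np.ndarray,
) -> dict[str, dict[str, float]]:
    """Rank-normalized split-R̂ and effective sample size per parameter.

    ``draws`` maps parameter name → array of shape (chains, draws) (a bare
    array is treated as one unnamed parameter).  Chains that are constant
    and identical give NaN R̂ (degenerate, flagged by the caller); chains
    stuck at different constants give a huge R̂.
    """
    if not isinstance(draws, dict):
        draws = {"param": np.asarray(draws)}
    out: dict[str, dict[str, float]] = {"rhat": {}, "ess": {}}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(f"{name}: need draws shaped (chains >= 2, draws)")
        if arr.shape[1] < 100:
            raise ValueError(f"{name}: need >= 100 draws per chain")
        ds = az.convert_to_dataset(arr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(ds)["x"])
            ess = float(az.ess(ds)["x"])
        if np.isnan(rhat):
            # all-constant draws: distinguish identical (degenerate, NaN)
            # from distinct stuck chains (divergent, inf)
            if np.ptp(arr) > 0:
                rhat = np.inf
        out["rhat"][name] = rhat
        out["ess"][name] = ess
    return out
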