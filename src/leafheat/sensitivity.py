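"""One-at-a-time ±10% input-sensitivity analysis of the estimated C_p.

The inversion takes several quantities as *assumed known*: absorptance,
emissivity, the foil (reflected) temperature, irradiance, air temperature,
relative humidity and sample thickness.  An error in any of them propagates
into the fitted C_p.  This module quantifies that propagation the way it is
done experimentally: the observed trace is held fixed, one assumed input is
perturbed by ±10%, the model is refit, and the relative change in C_p is
reported.

Temperatures are perturbed on the Celsius scale (±10% of 20 °C is ∓2 K;
a ±10% change of a kelvin value would be a ±30 K absurdity).  Thickness
enters only through ρ·lt, i.e. it rescales C_p = k/(ρ·lt) directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import physics
from .inference import MCMCConfig, PriorSpec, fit_transient
from .simulate import EnvironmentTrace, LightProtocol, ThermalTrace
from .traits import SampleProperties

__all__ = [
    "FACTORS",
    "PerturbationSpec",
    "BaselineInputs",
    "perturb_inputs",
    "cp_sensitivity_table",
    "plot_sensitivity",
]

FACTORS = (
    "absorptance",
    "emissivity",
    "T_reflect",
    "irradiance",
    "T_air",
    "RH",
    "thickness",
)


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation: a named factor and a relative change (e.g. ±0.10).

    Temperature factors are scaled on the Celsius value; all others on
    their natural scale.
    """

    factor: str
    relative_change: float

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(
                f"unknown factor {self.factor!r}; choose from {FACTORS}"
            )
        if abs(self.relative_change) >= 1:
            raise ValueError("|relative change| must be < 1")


@dataclass(frozen=True)
class BaselineInputs:
    """The assumed-input bundle handed to the inversion."""

    protocol: LightProtocol
    env: EnvironmentTrace
    sample: SampleProperties


def _scale_celsius(T_kelvin: np.ndarray | float, rel: float):
    """Scale a temperature by (1 + rel) on the Celsius scale."""
    return (np.asarray(T_kelvin) - 273.15) * (1.0 + rel) + 273.15


def perturb_inputs(base: BaselineInputs, spec: PerturbationSpec) -> BaselineInputs:
    """Return a copy of the inputs with one factor scaled by (1 + change)."""
    r = spec.relative_change
    if r == 0:
        return base
    env, sample, protocol = base.env, base.sample, base.protocol
    if spec.factor == "irradiance":
        protocol = protocol.scaled(1.0 + r)
    elif spec.factor == "absorptance":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # perturbed alpha may exceed 1
            optics = physics.OpticalProperties(
                sample.optics.alpha * (1.0 + r), sample.optics.epsilon
            )
        sample = replace(sample, optics=optics)
    elif spec.factor == "emissivity":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            optics = physics.OpticalProperties(
                sample.optics.alpha, sample.optics.epsilon * (1.0 + r)
            )
        sample = replace(sample, optics=optics)
    elif spec.factor == "T_air":
        env = EnvironmentTrace(
            env.times, _scale_celsius(env.T_air, r), env.RH_air,
            env.T_reflect, env.P_atm,
        )
    elif spec.factor == "T_reflect":
        env = EnvironmentTrace(
            env.times, env.T_air, env.RH_air,
            _scale_celsius(env.T_reflect, r), env.P_atm,
        )
    elif spec.factor == "RH":
        env = EnvironmentTrace(
            env.times, env.T_air, np.clip(env.RH_air * (1.0 + r), 0.0, 1.0),
            env.T_reflect, env.P_atm,
        )
    elif spec.factor == "thickness":
        # thickness only enters through rho*lt = FW/area; scaling lt scales
        # the assumed fresh weight at fixed area
        sample = replace(sample, FW=sample.FW * (1.0 + r))
    return BaselineInputs(protocol=protocol, env=env, sample=sample)


def cp_sensitivity_table(
    trace: ThermalTrace,
    base: BaselineInputs,
    factors: tuple[str, ...] = FACTORS,
    relative_change: float = 0.10,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    fix_g_sw: float | None = 0.0,
    decimate_to_hz: float | None = 5.0,
) -> pd.DataFrame:
    """Refit C_p once per (factor, ±direction) and tabulate %ΔC_p.

    The observed trace and the MCMC seed are held fixed across all refits so
    the reported differences reflect the perturbed assumptions, not sampler
    noise.  Non-converged refits keep their number but are flagged in the
    ``converged`` column.

    Returns a DataFrame with one row per (factor, direction) plus the
    baseline row, columns: factor, direction, cp_mean, pct_change_cp,
    converged, rhat_max, rmse_K.
    """
    mcmc = mcmc or MCMCConfig()

    def _fit(inputs: BaselineInputs):
        return fit_transient(
            trace, inputs.protocol, inputs.env, inputs.sample.optics,
            priors=priors, mcmc=mcmc,
            mass_per_area=inputs.sample.mass_per_area,
            fix_g_sw=fix_g_sw, decimate_to_hz=decimate_to_hz,
        )

    baseline = _fit(base)
    if not baseline.converged:
        raise RuntimeError(
            "baseline fit did not converge; sensitivity table would be "
            "meaningless"
        )
    cp0 = baseline.mean["C_p"]
    rows = [{
        "factor": "baseline", "direction": 0.0, "cp_mean": cp0,
        "pct_change_cp": 0.0, "converged": True,
        "rhat_max": max(baseline.rhat.values()), "rmse_K": baseline.rmse,
    }]
    for factor in factors:
        for sign in (+1.0, -1.0):
            spec = PerturbationSpec(factor, sign * relative_change)
            res = _fit(perturb_inputs(base, spec))
            if not res.converged:
                warnings.warn(
                    f"refit for {factor} {sign * relative_change:+.0%} did "
                    "not converge; row flagged", stacklevel=2,
                )
            rows.append({
                "factor": factor,
                "direction": sign * relative_change,
                "cp_mean": res.mean["C_p"],
                "pct_change_cp": 100.0 * (res.mean["C_p"] - cp0) / cp0,
                "converged": res.converged,
                "rhat_max": max(res.rhat.values()),
                "rmse_K": res.rmse,
            })
    return pd.DataFrame(rows)


def plot_sensitivity(table: pd.DataFrame, ax=None):
    """Grouped bar chart of %ΔC_p per factor for the +10% / −10% directions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    data = table[table["factor"] != "baseline"]
    factors = list(dict.fromkeys(data["factor"]))
    x = np.arange(len(factors))
    width = 0.38
    for offset, sign, color, label in (
        (-width / 2, 1, "0.55", "+10%"),
        (+width / 2, -1, "white", "−10%"),
    ):
        vals = [
            float(data[(data["factor"] == f) & (data["direction"] * sign > 0)]
                  ["pct_change_cp"].iloc[0])
            for f in factors
        ]
        ax.bar(x + offset, vals, width, color=color, edgecolor="black",
               label=label)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(factors, rotation=30, ha="right")
    ax.set_ylabel(r"change in $C_p$ (%)")
    ax.legend(frameon=False)
    return ax
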