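"""Synthetic fixture generators reproducing the validation study designs.

Two reference designs are packaged:

* **Aluminum plate** — a black-painted plate of known thickness (1.335 mm),
  density (2484 kg m⁻³) and specific heat capacity (896 J kg⁻¹ K⁻¹, hence
  k = lt·ρ·C_p ≈ 2971 J m⁻² K⁻¹), absorptance 0.98 and emissivity 0.96,
  exposed to a 60 s pulse at 270 W m⁻² followed by 9 min of darkness.  The
  plate is dry (g_sw = 0); the long pulse compensates its large thermal
  inertia.
* **Leaf** — the routine protocol: a 10 s pulse at 270 W m⁻²
  (1250 µmol m⁻² s⁻¹ PPFD) followed by 110 s of darkness, with plausible
  leaf parameters (k ≈ 900 J m⁻² K⁻¹, g_bh ≈ 0.01, g_sw ≈ 0.002 m s⁻¹)
  and tomato-like geometry.

Both run in a dark 20 °C lab (T_reflect = T_air, RH 50%, standard
pressure), sampled at 25 Hz with 0.05 K Gaussian sensor noise — between
the camera noise floor (< 30 mK NETD) and thermocouple noise (~0.2 K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import physics
from .simulate import (
    EnvironmentTrace,
    LightProtocol,
    ThermalTrace,
    generate_synthetic_transient,
)
from .traits import SampleProperties

__all__ = [
    "Fixture",
    "ALUMINUM",
    "LEAF",
    "make_aluminum_fixture",
    "make_leaf_fixture",
]

#: Lab conditions shared by the packaged designs.
LAB_T_AIR = 293.15  # 20 °C setpoint
LAB_RH = 0.50  # documented default; the enclosure RH was not reported
LAB_P_ATM = 101325.0
DEFAULT_NOISE_SD = 0.05  # K


@dataclass(frozen=True)
class Fixture:
    """A complete synthetic experiment: inputs, truth, and the noisy trace."""

    trace: ThermalTrace
    protocol: LightProtocol
    env: EnvironmentTrace
    sample: SampleProperties
    truth: physics.EnergyBalanceParams
    noise_sd: float
    seed: int | None

    @property
    def true_cp(self) -> float:
        return self.truth.k / self.sample.mass_per_area


@dataclass(frozen=True)
class _PlateSpec:
    thickness_m: float = 0.001335
    density_kg_m3: float = 2484.0
    cp_true: float = 896.0
    alpha: float = 0.98
    epsilon: float = 0.96
    g_bh: float = 0.010  # fan-mixed enclosure, ~0.2 m s⁻¹ wind
    pulse_s: float = 60.0
    dark_s: float = 540.0
    irradiance: float = 270.0


@dataclass(frozen=True)
class _LeafSpec:
    k_true: float = 900.0
    g_bh: float = 0.010
    g_sw: float = 0.002
    alpha: float = 0.92
    epsilon: float = 0.97
    mass_per_area: float = 0.2467  # tomato-like FW/area (kg m⁻²)
    pulse_s: float = 10.0
    dark_s: float = 110.0
    irradiance: float = 270.0


ALUMINUM = _PlateSpec()
LEAF = _LeafSpec()


def _lab_env(t_end: float) -> EnvironmentTrace:
    return EnvironmentTrace.constant(
        T_air=LAB_T_AIR, RH_air=LAB_RH, T_reflect=LAB_T_AIR,
        P_atm=LAB_P_ATM, t_start=0.0, t_end=t_end, cadence=5.0,
    )


def make_aluminum_fixture(
    seed: int | None = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    sample_rate_hz: float = 25.0,
    spec: _PlateSpec = ALUMINUM,
) -> Fixture:
    """Synthetic replica of the aluminum-plate validation run."""
    protocol = LightProtocol(
        ((0.0, spec.pulse_s, spec.irradiance),
         (spec.pulse_s, spec.pulse_s + spec.dark_s, 0.0)),
        ppfd=(1250.0, 0.0),
    )
    env = _lab_env(protocol.t_end)
    optics = physics.OpticalProperties(spec.alpha, spec.epsilon)
    sample = SampleProperties.plate(
        lt=spec.thickness_m, rho=spec.density_kg_m3, area=0.005, optics=optics
    )
    cond = physics.Conductances(g_bh=spec.g_bh, g_sw=0.0)
    truth = physics.EnergyBalanceParams(
        k=spec.thickness_m * spec.density_kg_m3 * spec.cp_true,
        conductances=cond,
        mass_per_area=sample.mass_per_area,
    )
    trace = generate_synthetic_transient(
        truth, protocol, env, optics,
        noise_sd=noise_sd, seed=seed, sample_rate_hz=sample_rate_hz,
    )
    return Fixture(trace, protocol, env, sample, truth, noise_sd, seed)


def make_leaf_fixture(
    seed: int | None = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    sample_rate_hz: float = 25.0,
    k: float | None = None,
    g_bh: float | None = None,
    g_sw: float | None = None,
    spec: _LeafSpec = LEAF,
) -> Fixture:
    """Synthetic leaf run under the 10 s pulse / 110 s dark protocol.

    ``k``, ``g_bh``, ``g_sw`` override the default truth, e.g. for
    parameter-recovery sweeps across the physiological range.
    """
    protocol = LightProtocol(
        ((0.0, spec.pulse_s, spec.irradiance),
         (spec.pulse_s, spec.pulse_s + spec.dark_s, 0.0)),
        ppfd=(1250.0, 0.0),
    )
    env = _lab_env(protocol.t_end)
    optics = physics.OpticalProperties(spec.alpha, spec.epsilon)
    area = 0.0017348  # tomato-like leaf, m²
    sample = SampleProperties(
        FW=spec.mass_per_area * area, area=area, optics=optics
    )
    cond = physics.Conductances(
        g_bh=spec.g_bh if g_bh is None else g_bh,
        g_sw=spec.g_sw if g_sw is None else g_sw,
    )
    truth = physics.EnergyBalanceParams(
        k=spec.k_true if k is None else k,
        conductances=cond,
        mass_per_area=sample.mass_per_area,
    )
    trace = generate_synthetic_transient(
        truth, protocol, env, optics,
        noise_sd=noise_sd, seed=seed, sample_rate_hz=sample_rate_hz,
    )
    return Fixture(trace, protocol, env, sample, truth, noise_sd, seed)


def recovery_sweep_params(
    n: int, seed: int
) -> list[tuple[float, float, float]]:
    """(k, g_bh, g_sw) triples sampled uniformly over the physiological
    ranges k ∈ [400, 1500] J m⁻² K⁻¹, g_bh ∈ [0.005, 0.02], g_sw ∈
    [0.001, 0.005] m s⁻¹, for parameter-recovery studies."""
    rng = np.random.default_rng(seed)
    return [
        (
            float(rng.uniform(400.0, 1500.0)),
            float(rng.uniform(0.005, 0.02)),
            float(rng.uniform(0.001, 0.005)),
        )
        for _ in range(n)
    ]
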