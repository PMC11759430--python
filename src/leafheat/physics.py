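"""Instantaneous physics of the dynamic leaf energy balance.

The rate of change of leaf (or plate) temperature follows

    dT_leaf/dt = [ α I_s
                   + 2 ε θ (T_reflect⁴ − T_leaf⁴)
                   − 2 ρ_air C_s g_bh (T_leaf − T_air)
                   − 2 λ (0.622 ρ_air / P_atm) g_tot VPD ] / k

with g_tot = 1 / (1/g_sw + 1/g_bw) the series stomatal/boundary-layer
conductance to water vapour, and k = lt·ρ·C_p the areal heat capacity
(J m⁻² K⁻¹).  Short-wave radiation is absorbed on the illuminated face only;
long-wave, sensible and latent exchange act on both faces (factor 2).

This module provides the psychrometric helpers, the individual flux terms,
the ODE right-hand side and its steady-state root.  Everything is pure
computation on validated frozen dataclasses; time integration lives in
:mod:`leafheat.simulate`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .constants import (
    CP_AIR,
    EPSILON_WATER_AIR,
    GAS_CONSTANT,
    HEAT_TO_VAPOUR_RATIO,
    LATENT_HEAT_VAPORIZATION,
    MOLAR_MASS_AIR,
    STEFAN_BOLTZMANN,
)

__all__ = [
    "EnvironmentState",
    "OpticalProperties",
    "Conductances",
    "EnergyBalanceParams",
    "PsychrometricState",
    "saturation_vapour_pressure",
    "psychrometric_state",
    "series_conductance",
    "conductance_to_molar",
    "molar_to_conductance",
    "flux_components",
    "energy_balance_rhs",
    "equilibrium_temperature",
]

_T_MIN, _T_MAX = 200.0, 400.0


def _check_temperature(T: float, name: str) -> None:
    if not (_T_MIN < T < _T_MAX):
        raise ValueError(f"{name}={T!r} K outside plausible range ({_T_MIN}, {_T_MAX})")


@dataclass(frozen=True)
class EnvironmentState:
    """Atmospheric drivers of the energy balance at one instant.

    Parameters
    ----------
    T_air : float
        Air temperature (K).
    RH_air : float
        Relative humidity as a fraction in [0, 1].
    T_reflect : float
        Radiative temperature of the surroundings (K), measured from a
        crumpled aluminum foil imaged with emissivity set to 1.
    P_atm : float
        Atmospheric pressure (Pa).
    I_s : float
        Incident short-wave irradiance (W m⁻²).
    """

    T_air: float
    RH_air: float
    T_reflect: float
    P_atm: float = 101325.0
    I_s: float = 0.0

    def __post_init__(self) -> None:
        _check_temperature(self.T_air, "T_air")
        _check_temperature(self.T_reflect, "T_reflect")
        if not 0.0 <= self.RH_air <= 1.0:
            raise ValueError(f"RH_air={self.RH_air!r} must be a fraction in [0, 1]")
        if self.P_atm <= 0:
            raise ValueError("P_atm must be positive")
        if self.I_s < 0:
            raise ValueError("I_s must be nonnegative")


@dataclass(frozen=True)
class OpticalProperties:
    """Short-wave absorptance and long-wave emissivity of the sample.

    Both are dimensionless fractions.  Values above 1 are physically
    impossible for a real surface but are accepted with a warning because
    the one-at-a-time sensitivity analysis deliberately perturbs an
    assumed absorptance of 0.98 by +10%.
    """

    alpha: float
    epsilon: float

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("epsilon", self.epsilon)):
            if v < 0:
                raise ValueError(f"{name}={v!r} must be nonnegative")
            if v > 1:
                warnings.warn(
                    f"{name}={v:.4g} exceeds 1; acceptable only as a perturbed "
                    "assumption in sensitivity analysis",
                    stacklevel=3,
                )


@dataclass(frozen=True)
class Conductances:
    """Conductances governing sensible and latent exchange (m s⁻¹).

    ``g_bw`` is always derived from ``g_bh`` through the laminar-flow
    relation g_bh = 0.92 g_bw; it is not an independent degree of freedom.
    """

    g_bh: float
    g_sw: float
    g_bw: float = field(init=False)

    def __post_init__(self) -> None:
        if self.g_bh < 0 or self.g_sw < 0:
            raise ValueError("conductances must be nonnegative")
        object.__setattr__(self, "g_bw", self.g_bh / HEAT_TO_VAPOUR_RATIO)

    @property
    def g_total_water(self) -> float:
        """Series conductance of the stomatal + boundary-layer pathway."""
        return series_conductance(self.g_sw, self.g_bw)


@dataclass(frozen=True)
class EnergyBalanceParams:
    """The inferred parameter triple plus the derived specific heat capacity.

    ``C_p = k / mass_per_area`` (J kg⁻¹ K⁻¹) is available whenever the fresh
    mass per unit area (= lt·ρ, kg m⁻²) is known.
    """

    k: float
    conductances: Conductances
    mass_per_area: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("areal heat capacity k must be positive")
        if self.mass_per_area is not None and self.mass_per_area <= 0:
            raise ValueError("mass_per_area must be positive when given")

    @property
    def C_p(self) -> float | None:
        if self.mass_per_area is None:
            return None
        return self.k / self.mass_per_area


@dataclass(frozen=True)
class PsychrometricState:
    """Derived humid-air quantities at a (T_leaf, environment) pair."""

    es: float  # saturation vapour pressure at T_leaf (Pa)
    ea: float  # air vapour pressure (Pa)
    VPD: float  # leaf-to-air vapour pressure difference (Pa)
    rho_air: float  # air density (kg m⁻³)
    C_s: float  # specific heat capacity of humid air (J kg⁻¹ K⁻¹)
    lam: float  # latent heat of vaporization (J kg⁻¹)


def saturation_vapour_pressure(T: float) -> float:
    """Saturation vapour pressure over liquid water (Pa), Tetens formula.

    es(T) = 610.78 · exp(17.27 (T − 273.15) / (T − 273.15 + 237.3))

    Accurate to ~1 Pa near 0 °C and well under 1% over the 0–50 °C range
    relevant for leaf work.
    """
    _check_temperature(T, "T")
    t_c = T - 273.15
    return 610.78 * math.exp(17.27 * t_c / (t_c + 237.3))


def air_density(T_air: float, P_atm: float) -> float:
    """Dry-air ideal-gas density ρ = P M / (R T) in kg m⁻³."""
    if P_atm <= 0:
        raise ValueError("P_atm must be positive")
    _check_temperature(T_air, "T_air")
    return P_atm * MOLAR_MASS_AIR / (GAS_CONSTANT * T_air)


def psychrometric_state(
    T_leaf: float,
    env: EnvironmentState,
    C_s: float = CP_AIR,
    lam: float = LATENT_HEAT_VAPORIZATION,
) -> PsychrometricState:
    """Evaluate es, ea, VPD, air density and the humid-air coefficients.

    The vapour pressure deficit driving transpiration is taken between the
    saturated leaf interior at ``T_leaf`` and the ambient air:
    VPD = es(T_leaf) − RH_air·es(T_air).  Air density follows the ideal gas
    law at (T_air, P_atm); C_s and λ are constant coefficients at lab
    temperature, overridable here and through the run configuration.
    """
    _check_temperature(T_leaf, "T_leaf")
    es_leaf = saturation_vapour_pressure(T_leaf)
    ea = env.RH_air * saturation_vapour_pressure(env.T_air)
    return PsychrometricState(
        es=es_leaf,
        ea=ea,
        VPD=es_leaf - ea,
        rho_air=air_density(env.T_air, env.P_atm),
        C_s=C_s,
        lam=lam,
    )


def series_conductance(g_sw: float, g_bw: float) -> float:
    """Series combination 1/(1/g_sw + 1/g_bw), with the closed-stomata limit.

    Returns 0 when either conductance is 0 (the transpiration pathway is
    blocked); this is the defined limit, not a division error, and is what
    makes a dry plate (g_sw = 0) a valid sample.
    """
    if g_sw < 0 or g_bw < 0:
        raise ValueError("conductances must be nonnegative")
    if g_sw == 0.0 or g_bw == 0.0:
        return 0.0
    return 1.0 / (1.0 / g_sw + 1.0 / g_bw)


def conductance_to_molar(
    g: float, T_leaf: float, P_atm: float, include_092: bool = False
) -> float:
    """Convert a conductance from m s⁻¹ to mol m⁻² s⁻¹.

    The conversion divides by the molar volume RT/P.  With
    ``include_092=True`` the stomatal-conductance variant divides by
    0.92·RT/P instead — both conventions are found in the thermography
    literature, so the choice is explicit here.
    """
    if g < 0:
        raise ValueError("conductance must be nonnegative")
    if T_leaf <= 0 or P_atm <= 0:
        raise ValueError("temperature and pressure must be positive")
    factor = GAS_CONSTANT * T_leaf / P_atm
    if include_092:
        factor *= HEAT_TO_VAPOUR_RATIO
    return g / factor


def molar_to_conductance(
    g_mol: float, T_leaf: float, P_atm: float, include_092: bool = False
) -> float:
    """Inverse of :func:`conductance_to_molar` (mol m⁻² s⁻¹ → m s⁻¹)."""
    if g_mol < 0:
        raise ValueError("conductance must be nonnegative")
    if T_leaf <= 0 or P_atm <= 0:
        raise ValueError("temperature and pressure must be positive")
    factor = GAS_CONSTANT * T_leaf / P_atm
    if include_092:
        factor *= HEAT_TO_VAPOUR_RATIO
    return g_mol * factor


def flux_components(
    T_leaf: float,
    env: EnvironmentState,
    optics: OpticalProperties,
    cond: Conductances,
    C_s: float = CP_AIR,
    lam: float = LATENT_HEAT_VAPORIZATION,
) -> dict[str, float]:
    """The four energy-flux terms (W m⁻²) at one instant.

    Returns
    -------
    dict with keys
        ``SW_abs``  absorbed short-wave, α·I_s (one face);
        ``LW_net``  net long-wave, 2εθ(T_reflect⁴ − T_leaf⁴) (both faces);
        ``H_sensible``  sensible loss, 2ρ_air·C_s·g_bh·(T_leaf − T_air);
        ``LE_latent``   latent loss, 2λ(0.622ρ_air/P_atm)·g_tot·VPD.
    Losses are positive when the leaf loses energy.
    """
    psy = psychrometric_state(T_leaf, env, C_s=C_s, lam=lam)
    sw = optics.alpha * env.I_s
    lw = 2.0 * optics.epsilon * STEFAN_BOLTZMANN * (env.T_reflect**4 - T_leaf**4)
    h = 2.0 * psy.rho_air * psy.C_s * cond.g_bh * (T_leaf - env.T_air)
    le = (
        2.0
        * psy.lam
        * (EPSILON_WATER_AIR * psy.rho_air / env.P_atm)
        * cond.g_total_water
        * psy.VPD
    )
    return {"SW_abs": sw, "LW_net": lw, "H_sensible": h, "LE_latent": le}


def energy_balance_rhs(
    T_leaf: float,
    env: EnvironmentState,
    optics: OpticalProperties,
    cond: Conductances,
    k: float,
    C_s: float = CP_AIR,
    lam: float = LATENT_HEAT_VAPORIZATION,
) -> float:
    """dT_leaf/dt (K s⁻¹): net flux divided by the areal heat capacity k."""
    if k <= 0:
        raise ValueError("areal heat capacity k must be positive")
    f = flux_components(T_leaf, env, optics, cond, C_s=C_s, lam=lam)
    return (f["SW_abs"] + f["LW_net"] - f["H_sensible"] - f["LE_latent"]) / k


def equilibrium_temperature(
    env: EnvironmentState,
    optics: OpticalProperties,
    cond: Conductances,
    C_s: float = CP_AIR,
    lam: float = LATENT_HEAT_VAPORIZATION,
) -> float:
    """Steady-state temperature: the root of the energy balance in T_leaf.

    Bracketed within [T_air − 30, T_air + 50] K and solved to machine
    precision with Brent's method.  The right-hand side is strictly
    decreasing in T_leaf (radiative, sensible and latent losses all grow
    with temperature), so the root is unique whenever g_bh > 0.
    """
    if cond.g_bh <= 0:
        raise ValueError("equilibrium requires g_bh > 0")

    def f(T: float) -> float:
        # k only scales the rhs; use k=1 so the root is unchanged
        return energy_balance_rhs(T, env, optics, cond, k=1.0, C_s=C_s, lam=lam)

    lo, hi = env.T_air - 30.0, env.T_air + 50.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            "no sign change of the energy balance in "
            f"[{lo:.1f}, {hi:.1f}] K (f(lo)={flo:.3g}, f(hi)={fhi:.3g}); "
            "inputs are outside the physically meaningful regime"
        )
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-15))
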