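"""Leaf trait calculators: water content, mass per area, SLA/LMA, water
loss, and the reference-emittance emissivity estimator.

These are the quick bench measurements that accompany each thermography
run: fresh and dry weights, one-sided leaf area, and the long-wave
emissivity estimated against a co-imaged water surface.  Internal units are
SI (kg, m²); gram/cm² convenience conversion happens at the I/O layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .constants import STEFAN_BOLTZMANN, WATER_EMISSIVITY  # noqa: F401
from .physics import OpticalProperties

__all__ = [
    "SampleProperties",
    "EmissivityMeasurement",
    "leaf_water_content",
    "mass_per_area_and_sla",
    "lma",
    "water_loss_percent",
    "leaf_emissivity",
]

#: Water-loss fraction above which a run is considered compromised by
#: desiccation during the imaging protocol.
WATER_LOSS_WARN_PCT = 4.0


@dataclass(frozen=True)
class SampleProperties:
    """Optics and geometry of a measured sample (leaf or reference plate).

    ``mass_per_area`` — fresh weight over one-sided area — is the lumped
    ρ·lt term that converts the fitted areal heat capacity k into the
    specific heat capacity C_p.  When independent thickness ``lt`` and
    density ``rho`` measurements exist they should satisfy
    lt·rho ≈ FW/area.
    """

    FW: float  # fresh weight (kg)
    area: float  # one-sided area (m²)
    optics: OpticalProperties
    DW: float | None = None  # dry weight (kg)
    lt: float | None = None  # thickness (m)
    rho: float | None = None  # density (kg m⁻³)

    def __post_init__(self) -> None:
        if self.FW <= 0 or self.area <= 0:
            raise ValueError("FW and area must be positive")
        if self.DW is not None and not (0 <= self.DW <= self.FW):
            raise ValueError("DW must satisfy 0 <= DW <= FW")
        if self.lt is not None and self.lt <= 0:
            raise ValueError("thickness must be positive")
        if self.rho is not None and self.rho <= 0:
            raise ValueError("density must be positive")
        if self.lt is not None and self.rho is not None:
            implied = self.lt * self.rho
            if not math.isclose(implied, self.mass_per_area, rel_tol=0.25):
                warnings.warn(
                    f"lt*rho = {implied:.4g} kg/m2 disagrees with FW/area = "
                    f"{self.mass_per_area:.4g} kg/m2 by more than 25%",
                    stacklevel=3,
                )

    @property
    def mass_per_area(self) -> float:
        """Fresh mass per unit area, FW/area = ρ·lt (kg m⁻²)."""
        return self.FW / self.area

    @classmethod
    def plate(
        cls, lt: float, rho: float, area: float, optics: OpticalProperties
    ) -> "SampleProperties":
        """A homogeneous reference plate of known thickness and density."""
        return cls(FW=lt * rho * area, area=area, optics=optics, lt=lt, rho=rho)


@dataclass(frozen=True)
class EmissivityMeasurement:
    """One reference-emittance observation: a leaf floating on warm water
    imaged together with the water surface and a crumpled-foil background."""

    T_water: float  # true-emissivity water surface temperature (K)
    T_l_app: float  # apparent leaf temperature at the reference emissivity (K)
    T_reflect: float  # foil (surroundings) radiative temperature (K)
    eps_reference: float = WATER_EMISSIVITY

    def __post_init__(self) -> None:
        if not 0 < self.eps_reference <= 1:
            raise ValueError("eps_reference must be in (0, 1]")


def leaf_water_content(FW: float, DW: float) -> float:
    """LWC (%) = 100·(FW − DW)/FW."""
    if FW <= 0:
        raise ValueError("FW must be positive")
    if not 0 <= DW <= FW:
        raise ValueError("DW must satisfy 0 <= DW <= FW")
    return 100.0 * (FW - DW) / FW


def mass_per_area_and_sla(FW: float, area: float) -> tuple[float, float]:
    """(ρ·lt, SLA_FW): fresh mass per area (kg m⁻²) and its reciprocal,
    the fresh-weight specific leaf area (m² kg⁻¹)."""
    if FW <= 0 or area <= 0:
        raise ValueError("FW and area must be positive")
    mpa = FW / area
    return mpa, 1.0 / mpa


def lma(DW: float | None, area: float) -> float | None:
    """Leaf dry mass per area (g m⁻²); ``None`` propagates missing DW."""
    if area <= 0:
        raise ValueError("area must be positive")
    if DW is None:
        return None
    if DW <= 0:
        raise ValueError("DW must be positive when present")
    return 1000.0 * DW / area


def water_loss_percent(FW_before: float, FW_after: float) -> float:
    """Water lost during the imaging protocol, % of initial fresh weight.

    Warns above 4% — beyond that the sample dried noticeably during the
    run and the fitted C_p no longer reflects the initial hydration state.
    """
    if FW_before <= 0:
        raise ValueError("FW_before must be positive")
    if not 0 < FW_after <= FW_before:
        raise ValueError("need 0 < FW_after <= FW_before")
    loss = 100.0 * (FW_before - FW_after) / FW_before
    if loss > WATER_LOSS_WARN_PCT:
        warnings.warn(
            f"water loss {loss:.1f}% exceeds {WATER_LOSS_WARN_PCT}%; "
            "C_p estimate may be biased by desiccation", stacklevel=2,
        )
    return loss


def leaf_emissivity(m: EmissivityMeasurement) -> float:
    """Long-wave emissivity by the reference-emittance technique:

    ε_leaf = ε_reference · (T_l,app⁴ − T_reflect⁴) / (T_water⁴ − T_reflect⁴)

    assuming the floating leaf is at water temperature; clipped to [0, 1]
    with a warning when measurement noise pushes it outside.
    """
    denom = m.T_water**4 - m.T_reflect**4
    if denom == 0:
        raise ValueError("T_water must differ from T_reflect")
    eps = m.eps_reference * (m.T_l_app**4 - m.T_reflect**4) / denom
    if not 0.0 <= eps <= 1.0:
        warnings.warn(
            f"estimated emissivity {eps:.3f} outside [0, 1]; clipping "
            "(check temperature readings)", stacklevel=2,
        )
        eps = min(max(eps, 0.0), 1.0)
    return eps
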