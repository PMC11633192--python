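"""Headspace/dissolved N₂O partitioning by Bunsen solubility equilibrium.

A sealed serum bottle holds ``v_liquid`` mL of medium under ``v_headspace`` mL
of gas.  At equilibrium the dissolved N₂O amount is α·(v_liquid/v_headspace)
times the headspace amount, where α is the Bunsen absorption coefficient
(volume of gas dissolved per volume of liquid at unit partial pressure;
α = 0.544 for N₂O at 25 °C).  Only the headspace is sampled by GC, so total
per-bottle N₂O is recovered as

    n_total = n_headspace · (1 + α·v_liquid/v_headspace)

α is treated as a configuration scalar; no solubility–temperature correlation
or salinity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["VesselGeometry", "total_n2o", "dissolved_n2o", "dissolved_fraction", "ppmv_to_umol"]

_R_ML_ATM = 82.0574  # mL·atm·mol⁻¹·K⁻¹


@dataclass(frozen=True)
class VesselGeometry:
    """Culture-vessel geometry and gas-partition constants.

    Defaults describe the standard incubation: 20 mL anoxic medium in a 50 mL
    serum bottle (30 mL headspace) at 25 °C, 1 atm, α = 0.544.
    """

    v_liquid: float = 20.0  # mL
    v_headspace: float = 30.0  # mL
    temperature: float = 25.0  # °C
    bunsen_alpha: float = 0.544
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.v_liquid <= 0 or self.v_headspace <= 0:
            raise ValidationError("vessel volumes must be positive")
        if self.bunsen_alpha < 0:
            raise ValidationError("Bunsen coefficient must be >= 0")
        if self.pressure_atm <= 0:
            raise ValidationError("pressure must be positive")


def dissolved_n2o(n_headspace: float, geom: VesselGeometry) -> float:
    """N₂O dissolved in the medium (µmol) at equilibrium with the headspace."""
    if n_headspace < 0:
        raise ValidationError(f"headspace amount must be >= 0, got {n_headspace}")
    return n_headspace * (geom.bunsen_alpha * geom.v_liquid / geom.v_headspace)


def total_n2o(n_headspace: float, geom: VesselGeometry) -> float:
    """Total per-bottle N₂O (µmol) from the measured headspace amount (µmol).

    Computed as headspace + dissolved in one addition, so the conservation
    identity headspace + :func:`dissolved_n2o` = total holds exactly (to the
    last bit) rather than merely to rounding.
    """
    return n_headspace + dissolved_n2o(n_headspace, geom)


def dissolved_fraction(geom: VesselGeometry) -> float:
    """Fraction of total N₂O residing in the liquid phase, in [0, 1)."""
    av = geom.bunsen_alpha * geom.v_liquid
    return av / (geom.v_headspace + av)


def ppmv_to_umol(ppmv: float, geom: VesselGeometry) -> float:
    """Convert a GC headspace mixing ratio (ppmv) to µmol in the headspace.

    Ideal gas at the vessel temperature and pressure (1 atm default; the
    incubation pressure is configurable on :class:`VesselGeometry`).
    """
    if ppmv < 0:
        raise ValidationError(f"mixing ratio must be >= 0, got {ppmv}")
    t_kelvin = geom.temperature + 273.15
    return ppmv * geom.pressure_atm * geom.v_headspace / (_R_ML_ATM * t_kelvin)
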