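"""Convective heat and mass transfer coefficients at the air-foam interface.

Laminar flat-plate correlations (Nu = 0.664 Re^1/2 Pr^1/3 and its mass
analogue for Sh) give the heat-transfer coefficient h and mass-transfer
coefficient h_m from the air state and a characteristic length d (by
convention here the foam thickness).  h is obtained from h_m through the
Chilton-Colburn analogy h = h_m rho c_p (alpha/D_AB)^(2/3); the direct
route h = Nu k / d is retained as a diagnostic cross-check, and the two
agree to within a couple of percent for gas-like Pr and Sc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .thermophys import thermal_diffusivity_air, vapor_diffusivity_air

__all__ = [
    "AirStream",
    "TransferCoefficients",
    "reynolds",
    "dimensionless_groups",
    "transfer_coefficients",
]

#: Upper Re bound for the laminar flat-plate correlation.
LAMINAR_RE_LIMIT = 5e5


@dataclass(frozen=True)
class AirStream:
    """Drying-air state. Defaults follow the study's fixed air constants."""

    temperature: float  # deg C
    velocity: float = 1.0  # m/s
    density: float = 1.073  # kg/m^3
    dynamic_viscosity: float = 19.907e-6  # Pa s
    conductivity: float = 0.0287  # W/(m K)
    specific_heat: float = 1005.04  # J/(kg K)
    pressure: float = 101325.0  # Pa
    ambient_moisture_concentration: float = 0.0  # mol/m^3 (dry air)

    def __post_init__(self) -> None:
        for name in (
            "density",
            "dynamic_viscosity",
            "conductivity",
            "specific_heat",
            "pressure",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"air {name} must be positive")
        if self.velocity < 0:
            raise ValueError("air velocity must be nonnegative")
        if self.ambient_moisture_concentration < 0:
            raise ValueError("ambient moisture concentration must be >= 0")


@dataclass(frozen=True)
class TransferCoefficients:
    """Dimensionless groups and transfer coefficients for one air state."""

    re: float
    pr: float
    sc: float
    nu: float
    sh: float
    d_ab: float  # m^2/s
    alpha: float  # m^2/s
    h: float  # W/(m^2 K), Chilton-Colburn route
    h_m: float  # m/s
    h_nu: float  # W/(m^2 K), Nu k / d diagnostic route
    characteristic_length: float  # m

    def as_dict(self) -> dict[str, float]:
        return {
            "Re": self.re,
            "Pr": self.pr,
            "Sc": self.sc,
            "Nu": self.nu,
            "Sh": self.sh,
            "D_AB_m2_s": self.d_ab,
            "alpha_m2_s": self.alpha,
            "h_W_m2K": self.h,
            "h_m_m_s": self.h_m,
            "h_from_Nu_W_m2K": self.h_nu,
            "characteristic_length_m": self.characteristic_length,
        }


def reynolds(air: AirStream, d: float) -> float:
    """Reynolds number Re = rho u d / mu."""
    if d < 0:
        raise ValueError("characteristic length d must be nonnegative")
    return air.density * air.velocity * d / air.dynamic_viscosity


def dimensionless_groups(air: AirStream, d: float = 0.005) -> TransferCoefficients:
    """Re, Pr, Sc, Nu, Sh plus the two molecular diffusivities.

    Pr = c_p mu / k; Sc = mu / (rho D_AB) with D_AB from the empirical
    vapor-diffusivity correlation at the air temperature and pressure;
    Nu and Sh via the 0.664 laminar flat-plate forms.  Warns outside the
    laminar range (Re > 5e5).
    """
    re = reynolds(air, d)
    if re > LAMINAR_RE_LIMIT:
        warnings.warn(
            f"Re = {re:.3g} exceeds the laminar flat-plate range ({LAMINAR_RE_LIMIT:g})",
            stacklevel=2,
        )
    d_ab = vapor_diffusivity_air(air.temperature, air.pressure)
    if d_ab <= 0:
        raise ValueError("nonpositive vapor diffusivity")
    pr = air.specific_heat * air.dynamic_viscosity / air.conductivity
    sc = air.dynamic_viscosity / (air.density * d_ab)
    nu = 0.664 * re**0.5 * pr ** (1.0 / 3.0)
    sh = 0.664 * re**0.5 * sc ** (1.0 / 3.0)
    alpha = thermal_diffusivity_air(air.conductivity, air.density, air.specific_heat)
    return TransferCoefficients(
        re=re,
        pr=pr,
        sc=sc,
        nu=nu,
        sh=sh,
        d_ab=d_ab,
        alpha=alpha,
        h=0.0,
        h_m=0.0,
        h_nu=0.0,
        characteristic_length=d,
    )


def transfer_coefficients(air: AirStream, d: float = 0.005) -> TransferCoefficients:
    """Complete coefficient set: h_m = Sh D_AB / d and the analogy-based h.

    h = h_m rho c_p (alpha/D_AB)^(2/3); the alternative h_nu = Nu k / d is
    computed alongside for consistency checking.
    """
    if d <= 0:
        raise ValueError("characteristic length d must be positive for h, h_m")
    groups = dimensionless_groups(air, d)
    h_m = groups.sh * groups.d_ab / d
    h = h_m * air.density * air.specific_heat * (groups.alpha / groups.d_ab) ** (2.0 / 3.0)
    h_nu = groups.nu * air.conductivity / d
    return TransferCoefficients(
        re=groups.re,
        pr=groups.pr,
        sc=groups.sc,
        nu=groups.nu,
        sh=groups.sh,
        d_ab=groups.d_ab,
        alpha=groups.alpha,
        h=h,
        h_m=h_m,
        h_nu=h_nu,
        characteristic_length=d,
    )
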