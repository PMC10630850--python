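"""Composition- and temperature-dependent foam thermophysical properties.

Food-engineering mixing rules evaluate foam density, specific heat and
thermal conductivity from the mass fractions of water, protein, fat,
carbohydrate, fiber and ash, with each pure-component property taken from
the Choi-Okos quadratic temperature polynomials (shipped as a CSV table in
``foamdry/data/choi_okos.csv`` and overridable by the user).  Air-side
vapor diffusivity and thermal diffusivity round out the inputs the
interface transfer-coefficient correlations need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENTS",
    "FoamComposition",
    "ComponentPropertySet",
    "FoamThermoState",
    "load_choi_okos",
    "foam_density",
    "foam_specific_heat",
    "foam_conductivity",
    "vapor_diffusivity_air",
    "thermal_diffusivity_air",
]

COMPONENTS = ("water", "protein", "fat", "carbohydrate", "fiber", "ash")

#: Offset used by the empirical vapor-diffusivity correlation (kept verbatim
#: from its source; everywhere else 273.15 converts deg C to K).
_VAPOR_DIFF_OFFSET = 273.18

#: Raw red beetroot proximate composition, g/100 g (wet basis).
BEETROOT_COMPOSITION = {
    "water": 86.26,
    "protein": 1.59,
    "fat": 0.15,
    "carbohydrate": 9.42,
    "fiber": 2.52,
    "ash": 1.00,
}


@dataclass(frozen=True)
class FoamComposition:
    """Mass fractions of the six proximate components, normalised to sum 1."""

    water: float
    protein: float = 0.0
    fat: float = 0.0
    carbohydrate: float = 0.0
    fiber: float = 0.0
    ash: float = 0.0

    def __post_init__(self) -> None:
        fracs = self.as_array()
        if np.any(fracs < 0):
            raise ValueError("mass fractions must be nonnegative")
        total = fracs.sum()
        if total <= 0:
            raise ValueError("composition must have positive total mass")
        if abs(total - 1.0) > 1e-6:
            fracs = fracs / total
            for name, value in zip(COMPONENTS, fracs):
                object.__setattr__(self, name, float(value))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in COMPONENTS], dtype=float)

    @classmethod
    def beetroot(cls) -> "FoamComposition":
        """Default raw red beetroot composition (proximate table)."""
        return cls(**{k: v / 100.0 for k, v in BEETROOT_COMPOSITION.items()})


def _default_table() -> pd.DataFrame:
    with resources.as_file(
        resources.files("foamdry").joinpath("data/choi_okos.csv")
    ) as p:
        return pd.read_csv(p)


def load_choi_okos(path: str | Path | None = None) -> pd.DataFrame:
    """Load a component-property coefficient table.

    The table has columns ``component, property, c0, c1, c2`` with each
    property evaluated as ``c0 + c1*T + c2*T**2`` (T in deg C, SI values).
    ``path=None`` loads the bundled Choi-Okos coefficients.
    """
    df = _default_table() if path is None else pd.read_csv(path)
    required = {"component", "property", "c0", "c1", "c2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coefficient table missing columns: {sorted(missing)}")
    return df


@dataclass
class ComponentPropertySet:
    """Per-component property polynomials evaluable at a temperature.

    Wraps a Choi-Okos-style coefficient table; `density`, `specific_heat`
    and `conductivity` return one value per component in COMPONENTS order.
    """

    table: pd.DataFrame = field(default_factory=_default_table)

    def __post_init__(self) -> None:
        self._coeffs: dict[str, np.ndarray] = {}
        for prop in ("density", "specific_heat", "conductivity"):
            rows = self.table[self.table["property"] == prop].set_index("component")
            missing = [c for c in COMPONENTS if c not in rows.index]
            if missing:
                raise ValueError(f"{prop}: no coefficients for {missing}")
            self._coeffs[prop] = rows.loc[list(COMPONENTS), ["c0", "c1", "c2"]].to_numpy(
                dtype=float
            )

    def _eval(self, prop: str, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        c = self._coeffs[prop]
        vals = (
            c[:, 0]
            + np.multiply.outer(T, c[:, 1])
            + np.multiply.outer(T**2, c[:, 2])
        )
        if np.any(vals <= 0):
            raise ValueError(f"nonpositive {prop} in the component table")
        return vals

    def density(self, T) -> np.ndarray:
        """Component densities at T (deg C), kg/m^3; component axis last."""
        return self._eval("density", T)

    def specific_heat(self, T) -> np.ndarray:
        """Component specific heats at T (deg C), J/(kg K)."""
        return self._eval("specific_heat", T)

    def conductivity(self, T) -> np.ndarray:
        """Component thermal conductivities at T (deg C), W/(m K)."""
        return self._eval("conductivity", T)


@dataclass(frozen=True)
class FoamThermoState:
    """Evaluated foam properties at one temperature."""

    density: float  # kg/m^3
    specific_heat: float  # J/(kg K)
    conductivity: float  # W/(m K)
    porosity: float
    temperature: float  # deg C

    def __post_init__(self) -> None:
        if not (0 <= self.porosity < 1):
            raise ValueError("porosity must lie in [0, 1)")
        for name in ("density", "specific_heat", "conductivity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def foam_density(
    comp: FoamComposition,
    eps: float,
    T: float,
    props: ComponentPropertySet | None = None,
    mixing: str = "as_printed",
) -> float:
    """Foam density, kg/m^3, at porosity ``eps`` and temperature ``T`` (degC).

    ``mixing="as_printed"`` (default) uses the arithmetic mass-fraction
    mixture rho = (1-eps) * sum(X_i rho_i); ``"harmonic"`` uses the
    conventional Choi-Okos form rho = (1-eps) / sum(X_i / rho_i).  The two
    agree exactly for a single-component material.
    """
    if not (0 <= eps <= 1):
        raise ValueError("porosity eps must lie in [0, 1]")
    if eps == 1.0:
        return 0.0
    props = props or ComponentPropertySet()
    x = comp.as_array()
    rho_i = props.density(T)
    if mixing == "as_printed":
        return float((1 - eps) * np.dot(x, rho_i))
    if mixing == "harmonic":
        return float((1 - eps) / np.dot(x, 1.0 / rho_i))
    raise ValueError(f"unknown mixing rule {mixing!r}")


def foam_specific_heat(
    comp: FoamComposition, T: float, props: ComponentPropertySet | None = None
) -> float:
    """Mass-fraction-weighted foam specific heat, J/(kg K)."""
    props = props or ComponentPropertySet()
    return float(np.dot(comp.as_array(), props.specific_heat(T)))


def foam_conductivity(
    comp: FoamComposition, T: float, props: ComponentPropertySet | None = None
) -> float:
    """Foam thermal conductivity, W/(m K).

    Component conductivities weighted by X_i * rho_i and normalised, so the
    result is bounded by the component extremes.
    """
    props = props or ComponentPropertySet()
    x = comp.as_array()
    w = x * props.density(T)
    return float(np.dot(w, props.conductivity(T)) / w.sum())


def vapor_diffusivity_air(T: float, P: float = 101325.0) -> float:
    """Water-vapor diffusivity in air, m^2/s.

    Empirical correlation D_AB = (2.26/P) * ((T + 273.18)/273.18)**1.81 with
    T in deg C and P in Pa; increasing in T, decreasing in P.
    """
    if P <= 0:
        raise ValueError("pressure P must be positive")
    if T < -_VAPOR_DIFF_OFFSET:
        raise ValueError("temperature below absolute zero")
    return (2.26 / P) * ((T + _VAPOR_DIFF_OFFSET) / _VAPOR_DIFF_OFFSET) ** 1.81


def thermal_diffusivity_air(k_inf: float, rho_inf: float, cp_inf: float) -> float:
    """Air thermal diffusivity alpha = k / (rho * c_p), m^2/s."""
    if k_inf <= 0 or rho_inf <= 0 or cp_inf <= 0:
        raise ValueError("k, rho and c_p must all be positive")
    return k_inf / (rho_inf * cp_inf)
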