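"""Powder characterisation: densities, porosity, flowability, hydration
indices, moisture content, and CIELAB-derived color indices.

Flowability classes follow the conventional Carr-index / Hausner-ratio
bands; the browning index uses the standard chromaticity-ratio form
BI = 100 (x - 0.31) / 0.17 with x = (a* + 1.75 L*) / (5.645 L* + a* - 3.012 b*).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "DensityMeasurement",
    "FlowabilityResult",
    "ColorTriplet",
    "ColorIndices",
    "densities",
    "porosity",
    "flowability",
    "water_indices",
    "powder_mc",
    "color_indices",
    "percent_change",
    "classify_carr_index",
    "classify_hausner_ratio",
]

# Flowability bands (lower edge, label), half-open [low, next_low); each
# band's upper edge extends to the next band's lower edge so every value
# classifies deterministically.
_CI_BANDS = [
    (0.0, "Excellent"),
    (11.0, "Good"),
    (16.0, "Fair"),
    (21.0, "Passable"),
    (26.0, "Poor"),
    (32.0, "Very poor"),
    (38.0, "Very, very poor"),
]
_HR_BANDS = [
    (1.0, "Excellent"),
    (1.12, "Good"),
    (1.19, "Fair"),
    (1.26, "Passable"),
    (1.35, "Poor"),
    (1.46, "Very poor"),
    (1.60, "Very, very poor"),
]


@dataclass(frozen=True)
class DensityMeasurement:
    """Raw masses/volumes for one powder replicate (toluene displacement
    for the solid volume)."""

    powder_mass: float  # g
    untapped_volume: float  # cm^3
    tapped_volume: float  # cm^3
    displaced_solid_volume: float  # cm^3

    def __post_init__(self) -> None:
        if self.powder_mass <= 0:
            raise ValueError("powder mass must be positive")
        for name in ("untapped_volume", "tapped_volume", "displaced_solid_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tapped_volume > self.untapped_volume:
            raise ValueError("tapped volume cannot exceed untapped volume")
        if self.displaced_solid_volume > self.tapped_volume:
            raise ValueError("solid volume cannot exceed tapped volume")


@dataclass(frozen=True)
class FlowabilityResult:
    """Carr index, Hausner ratio and their flow-class labels."""

    carr_index: float  # %
    hausner_ratio: float
    ci_class: str
    hr_class: str
    agreement: bool  # do the two classifications coincide?


@dataclass(frozen=True)
class ColorTriplet:
    """CIELAB coordinates: L* lightness in [0, 100], a* red-green,
    b* yellow-blue."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.L <= 100.0):
            raise ValueError("L* must lie in [0, 100]")


@dataclass(frozen=True)
class ColorIndices:
    """Derived color indices; hue is None when a* = b* = 0."""

    delta_e: float | None  # None when no reference given
    chroma: float
    hue_deg: float | None  # (-180, 180]
    browning_index: float
    chromaticity_x: float  # the intermediate ratio in the BI formula


def densities(m: DensityMeasurement) -> tuple[float, float, float]:
    """(bulk, tapped, particle) densities in g/cm^3.

    Mass over untapped, tapped and displaced solid volume respectively;
    warns (does not fail) if the expected ordering rho_B <= rho_T <= rho_P
    is violated.
    """
    rho_b = m.powder_mass / m.untapped_volume
    rho_t = m.powder_mass / m.tapped_volume
    rho_p = m.powder_mass / m.displaced_solid_volume
    if not (rho_b <= rho_t <= rho_p):
        warnings.warn(
            f"unexpected density ordering: bulk={rho_b:.3g}, tapped={rho_t:.3g}, "
            f"particle={rho_p:.3g}",
            stacklevel=2,
        )
    return rho_b, rho_t, rho_p


def porosity(rho_b: float, rho_p: float) -> float:
    """Bulk porosity eps = 1 - rho_B / rho_P."""
    if rho_p == 0:
        raise ValueError("particle density must be nonzero")
    return 1.0 - rho_b / rho_p


def classify_carr_index(ci: float) -> str:
    if ci < 0:
        raise ValueError("Carr index cannot be negative")
    label = _CI_BANDS[0][1]
    for low, name in _CI_BANDS:
        if ci >= low:
            label = name
    return label


def classify_hausner_ratio(hr: float) -> str:
    if hr < 1.0:
        raise ValueError("Hausner ratio cannot be below 1")
    label = _HR_BANDS[0][1]
    for low, name in _HR_BANDS:
        if hr >= low:
            label = name
    return label


def flowability(rho_b: float, rho_t: float) -> FlowabilityResult:
    """Carr index CI = 100 (rho_T - rho_B)/rho_T, Hausner ratio
    HR = rho_T/rho_B, plus flow-class labels.

    The identity CI = 100 (1 - 1/HR) holds exactly by construction.
    """
    if rho_b <= 0 or rho_t <= 0:
        raise ValueError("densities must be positive")
    if rho_t < rho_b:
        raise ValueError(
            "tapped density below bulk density is physically impossible"
        )
    ci = 100.0 * (rho_t - rho_b) / rho_t
    hr = rho_t / rho_b
    ci_class = classify_carr_index(ci)
    hr_class = classify_hausner_ratio(hr)
    return FlowabilityResult(
        carr_index=ci,
        hausner_ratio=hr,
        ci_class=ci_class,
        hr_class=hr_class,
        agreement=ci_class == hr_class,
    )


def water_indices(
    residue_mass: float, supernatant_dry_mass: float, sample_dry_mass: float
) -> tuple[float, float]:
    """(WAI, WSI%) from the centrifugation assay.

    WAI = hydrated residue mass / dry sample mass (dimensionless);
    WSI = 100 * dried supernatant mass / dry sample mass (%).
    """
    if sample_dry_mass <= 0:
        raise ValueError("sample dry mass must be positive")
    if residue_mass < 0 or supernatant_dry_mass < 0:
        raise ValueError("masses must be nonnegative")
    return (
        residue_mass / sample_dry_mass,
        100.0 * supernatant_dry_mass / sample_dry_mass,
    )


def powder_mc(w1: float, w2: float) -> float:
    """Wet-basis moisture content, %: 100 (w1 - w2)/w1 for masses before
    (w1) and after (w2) oven drying."""
    if w1 <= 0:
        raise ValueError("initial mass w1 must be positive")
    if w2 < 0 or w2 > w1:
        raise ValueError("dried mass w2 must lie in [0, w1]")
    return 100.0 * (w1 - w2) / w1


def color_indices(
    sample: ColorTriplet, reference: ColorTriplet | None = None
) -> ColorIndices:
    """Chroma, hue angle, browning index and (given a reference) Delta-E.

    Chroma C* = sqrt(a*^2 + b*^2); hue via the quadrant-aware arctangent in
    degrees (None with a warning when a* = b* = 0); Delta-E is the Euclidean
    distance in L*a*b* to the reference triplet.
    """
    a, b, L = sample.a, sample.b, sample.L
    chroma = math.hypot(a, b)
    if a == 0 and b == 0:
        warnings.warn("hue angle undefined for a* = b* = 0", stacklevel=2)
        hue = None
    else:
        hue = math.degrees(math.atan2(b, a))
    denom = 5.645 * L + a - 3.012 * b
    if denom <= 0:
        raise ValueError(
            f"browning-index denominator {denom:.4g} <= 0 for L*={L}, a*={a}, b*={b}"
        )
    x = (a + 1.75 * L) / denom
    bi = 100.0 * (x - 0.31) / 0.17
    delta_e = None
    if reference is not None:
        delta_e = math.sqrt(
            (reference.L - L) ** 2 + (reference.a - a) ** 2 + (reference.b - b) ** 2
        )
    return ColorIndices(
        delta_e=delta_e,
        chroma=chroma,
        hue_deg=hue,
        browning_index=bi,
        chromaticity_x=x,
    )


def percent_change(before: float, after: float, direction: str | None = None) -> float:
    """Relative change 100 |after - before| / before, %.

    ``direction`` ("increase" or "decrease") validates the sign of the
    observed change; a mismatch raises.
    """
    if before == 0:
        raise ValueError("undefined percent change from a zero baseline")
    if direction is not None:
        if direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")
        if direction == "increase" and after < before:
            raise ValueError(f"expected an increase but {after} < {before}")
        if direction == "decrease" and after > before:
            raise ValueError(f"expected a decrease but {after} > {before}")
    return 100.0 * abs(after - before) / abs(before)
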