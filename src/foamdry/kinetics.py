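"""Drying-curve kinetics: moisture ratio, drying rate, and the two-stage
estimation chain (Crank-slope effective diffusivity, Arrhenius activation
energy).

The workflow mirrors standard thin-layer drying analysis for a foam slab of
thickness ``L`` dried from one face:

1. normalise each curve to a moisture ratio MR(t) = (X - X_e)/(X_i - X_e)
   (or the simplified X/X_i when the equilibrium moisture is negligible);
2. in the falling-rate period MR follows the Crank infinite-slab series, whose
   one-term truncation gives ln MR = ln(8/pi^2) - (pi^2 D_eff / 4 L^2) t, so
   an OLS slope of ln MR on t yields D_eff;
3. D_eff(T) across air temperatures follows an Arrhenius law
   D_eff = D_0 exp(-E_a / R T), so an OLS slope of ln D_eff on 1/T yields the
   activation energy E_a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DryingCurve",
    "KineticsFit",
    "ArrheniusFit",
    "GAS_CONSTANT",
    "compute_mr",
    "compute_dr",
    "crank_mr",
    "fit_deff",
    "fit_activation_energy",
]

#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.314

#: Celsius -> Kelvin offset used for the Arrhenius temperature axis.
KELVIN_OFFSET = 273.15

#: Default ln(MR) fit window as (upper, lower) MR bounds: drop the initial
#: warm-up point (MR near 1) and the near-equilibrium noise floor, where the
#: one-term Crank truncation is invalid or the log-noise blows up.
DEFAULT_MR_WINDOW = (0.95, 0.02)


@dataclass(frozen=True)
class DryingCurve:
    """A time-ordered drying curve at one air temperature.

    Parameters
    ----------
    times : array-like of float
        Sampling times in seconds, strictly increasing, first value >= 0.
    moisture : array-like of float
        Dry-basis moisture content X (kg water / kg dry solid), nonnegative.
    air_temperature : float
        Drying-air temperature in deg C.
    thickness_L : float
        Foam layer thickness in metres (> 0).
    label : str
        Free-text identifier.
    """

    times: np.ndarray
    moisture: np.ndarray
    air_temperature: float
    thickness_L: float = 0.005
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.moisture, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "moisture", x)
        if t.ndim != 1 or x.ndim != 1:
            raise ValueError("times and moisture must be 1-D")
        if len(t) != len(x):
            raise ValueError(
                f"length mismatch: {len(t)} times vs {len(x)} moisture values"
            )
        if len(t) == 0:
            raise ValueError("empty drying curve")
        if t[0] < 0:
            raise ValueError("times must start at >= 0")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(x < 0):
            raise ValueError("dry-basis moisture must be nonnegative")
        if not self.thickness_L > 0:
            raise ValueError("thickness_L must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class KineticsFit:
    """Result of the Crank-slope effective-diffusivity estimate."""

    deff: float  # m^2/s
    slope: float  # 1/s, negative
    intercept: float  # dimensionless, ln MR at t=0
    r_squared: float
    n_points_used: int
    mr_window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.deff > 0:
            raise ValueError("deff must be positive")
        if not self.slope < 0:
            raise ValueError("slope must be negative")


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius parameters of D_eff(T): D_eff = d0 * exp(-ea / (R T))."""

    ea: float  # J/mol
    d0: float  # m^2/s
    slope_k2: float  # K (= ea / R, magnitude of the ln D vs 1/T slope)
    r_squared: float


def compute_mr(
    curve: DryingCurve, xe: float = 0.0, simplified: bool = True
) -> np.ndarray:
    """Moisture ratio series for a drying curve.

    With ``simplified=True`` (default, appropriate when the equilibrium
    moisture is small next to X) MR = X(t)/X_i; otherwise
    MR = (X(t) - xe)/(X_i - xe) with X_i the first moisture value.
    """
    if xe < 0:
        raise ValueError("equilibrium moisture xe must be nonnegative")
    x = curve.moisture
    xi = x[0]
    if simplified:
        if xi == 0:
            raise ValueError("initial moisture X_i is zero; MR undefined")
        mr = x / xi
    else:
        if xi == xe:
            raise ValueError(
                "X_i equals xe: zero denominator in MR = (X - X_e)/(X_i - X_e)"
            )
        mr = (x - xe) / (xi - xe)
    if not np.all(np.isfinite(mr)):
        raise ValueError("non-finite moisture ratio encountered")
    return mr


def compute_dr(curve: DryingCurve) -> tuple[np.ndarray, float]:
    """Drying-rate magnitudes |dX/dt| per interval, in (kg/kg db)/min.

    Returns ``(rates, mean_rate)`` where ``rates`` has length ``n - 1``
    (forward differences) and ``mean_rate`` is their arithmetic mean, the
    per-run summary usually tabulated alongside MC and MR.
    """
    if len(curve) < 2:
        raise ValueError("drying rate needs at least 2 points")
    dt_min = np.diff(curve.times) / 60.0
    if np.any(dt_min == 0):
        raise ValueError("duplicate time stamps in drying curve")
    rates = np.abs(np.diff(curve.moisture)) / dt_min
    return rates, float(rates.mean())


def crank_mr(
    deff: float,
    L: float,
    t: float | Sequence[float] | np.ndarray,
    n_terms: int = 50,
) -> np.ndarray | float:
    """Crank infinite-slab moisture ratio, one-face drying.

    MR(t) = (8/pi^2) * sum_{N=0}^{n_terms-1} (2N+1)^-2
            * exp(-(2N+1)^2 pi^2 deff t / (4 L^2))

    The N=0 truncation is the usual one-term model for long drying times.
    Value lies in (0, 1]; at t=0 the full series sums to 1 exactly.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if L <= 0:
        raise ValueError("slab thickness L must be positive")
    if deff < 0:
        raise ValueError("deff must be nonnegative")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    n = np.arange(n_terms)[:, None]
    odd = 2 * n + 1
    terms = (1.0 / odd**2) * np.exp(
        -(odd**2) * math.pi**2 * deff * np.atleast_1d(t_arr)[None, :] / (4 * L**2)
    )
    mr = (8.0 / math.pi**2) * terms.sum(axis=0)
    if t_arr.ndim == 0:
        return float(mr[0])
    return mr


def fit_deff(
    curve: DryingCurve,
    xe: float = 0.0,
    mr_window: tuple[float, float] = DEFAULT_MR_WINDOW,
    simplified: bool = True,
) -> KineticsFit:
    """Estimate the effective moisture diffusivity by the Crank-slope method.

    Ordinary least squares of ln MR on t over the points whose MR lies inside
    ``mr_window = (upper, lower)``; D_eff = -slope * 4 L^2 / pi^2.

    Raises
    ------
    ValueError
        If fewer than 3 points fall in the window, if any in-window MR is
        nonpositive, or if the fitted slope is not negative.
    """
    upper, lower = mr_window
    if not upper > lower:
        raise ValueError("mr_window must be (upper, lower) with upper > lower")
    mr = compute_mr(curve, xe=xe, simplified=simplified)
    in_window = (mr <= upper) & (mr >= lower)
    bad = np.flatnonzero(in_window & (mr <= 0))
    if bad.size:
        raise ValueError(
            f"nonpositive MR inside fit window at rows {bad.tolist()}; "
            "cannot take ln(MR)"
        )
    idx = np.flatnonzero(in_window)
    if idx.size < 3:
        raise ValueError(
            f"only {idx.size} points with MR in window {mr_window}; need >= 3"
        )
    res = stats.linregress(curve.times[idx], np.log(mr[idx]))
    if not res.slope < 0:
        raise ValueError(
            f"ln(MR) slope is {res.slope:.3g} (not negative); "
            "curve shows no net drying"
        )
    deff = -res.slope * 4 * curve.thickness_L**2 / math.pi**2
    return KineticsFit(
        deff=deff,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points_used=int(idx.size),
        mr_window=mr_window,
    )


def fit_activation_energy(
    points: Sequence[tuple[float, float]],
) -> ArrheniusFit:
    """Arrhenius fit of effective diffusivity against air temperature.

    Parameters
    ----------
    points : sequence of (air_temperature_degC, deff_m2_per_s)
        At least two distinct temperatures; duplicate temperatures are pooled
        into the regression as-is.

    Returns
    -------
    ArrheniusFit
        With ea = -slope * R (J/mol) and d0 = exp(intercept) (m^2/s) from the
        OLS of ln(deff) on 1/(T + 273.15).
    """
    pts = [(float(T), float(d)) for T, d in points]
    if len(pts) < 2:
        raise ValueError("need diffusivities at >= 2 temperatures")
    temps = np.array([p[0] for p in pts])
    deffs = np.array([p[1] for p in pts])
    if np.unique(temps).size < 2:
        raise ValueError("need >= 2 distinct temperatures for an Arrhenius fit")
    if np.any(deffs <= 0):
        raise ValueError("all diffusivities must be positive")
    inv_T = 1.0 / (temps + KELVIN_OFFSET)
    res = stats.linregress(inv_T, np.log(deffs))
    ea = -res.slope * GAS_CONSTANT
    return ArrheniusFit(
        ea=float(ea),
        d0=float(math.exp(res.intercept)),
        slope_k2=float(abs(res.slope)),
        r_squared=float(res.rvalue**2),
    )
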