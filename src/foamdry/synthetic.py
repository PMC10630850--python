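"""Seeded synthetic-data generators.

These emulate the statistical structure the analysis stages assume —
falling-rate drying curves built from the Crank slab series (or the full
transport solver), exponential-approach foam temperature traces, and
replicate "mean +/- SD" measurement tables — so every pipeline stage is
testable without any external data.  All randomness flows through
``numpy.random.default_rng(seed)``; identical seeds give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .kinetics import DryingCurve, crank_mr

__all__ = [
    "CurveGenSpec",
    "ReplicateSpec",
    "generate_drying_curve",
    "generate_temperature_series",
    "generate_replicates",
    "TABLE_QUALITY_MEANS",
    "TABLE_QUALITY_SDS",
]

#: Study-condition powder-quality means by air temperature (deg C): the
#: ground truth the replicate generator perturbs.
TABLE_QUALITY_MEANS = {
    50: {
        "rho_B": 0.549, "rho_T": 0.623, "rho_P": 1.363, "porosity": 0.596,
        "CI": 11.917, "HR": 1.135, "WAI": 3.204, "WSI": 75.533, "MC": 6.308,
        "L": 36.306, "a": 32.515, "b": 5.567,
    },
    60: {
        "rho_B": 0.560, "rho_T": 0.627, "rho_P": 1.362, "porosity": 0.589,
        "CI": 10.739, "HR": 1.120, "WAI": 3.048, "WSI": 76.833, "MC": 6.200,
        "L": 38.929, "a": 31.559, "b": 4.690,
    },
    70: {
        "rho_B": 0.541, "rho_T": 0.603, "rho_P": 1.361, "porosity": 0.603,
        "CI": 10.386, "HR": 1.116, "WAI": 2.999, "WSI": 76.333, "MC": 6.092,
        "L": 38.967, "a": 30.233, "b": 4.278,
    },
}

#: Matching replicate standard deviations (the +/- columns).
TABLE_QUALITY_SDS = {
    50: {
        "rho_B": 0.003, "rho_T": 0.004, "rho_P": 0.011, "porosity": 0.005,
        "CI": 0.454, "HR": 0.006, "WAI": 0.260, "WSI": 1.007, "MC": 0.097,
        "L": 0.668, "a": 0.840, "b": 0.404,
    },
    60: {
        "rho_B": 0.003, "rho_T": 0.002, "rho_P": 0.006, "porosity": 0.003,
        "CI": 0.370, "HR": 0.005, "WAI": 0.188, "WSI": 0.961, "MC": 0.098,
        "L": 2.008, "a": 2.909, "b": 0.757,
    },
    70: {
        "rho_B": 0.003, "rho_T": 0.002, "rho_P": 0.020, "porosity": 0.004,
        "CI": 0.250, "HR": 0.003, "WAI": 0.151, "WSI": 0.757, "MC": 0.046,
        "L": 0.498, "a": 0.751, "b": 0.481,
    },
}

#: Physical lower/upper clip bounds per quantity (None = unbounded).
_CLIP_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "rho_B": (1e-6, None), "rho_T": (1e-6, None), "rho_P": (1e-6, None),
    "porosity": (0.0, 1.0), "CI": (0.0, 100.0), "HR": (1.0, None),
    "WAI": (0.0, None), "WSI": (0.0, 100.0), "MC": (0.0, 100.0),
    "L": (0.0, 100.0),
}


@dataclass(frozen=True)
class CurveGenSpec:
    """Recipe for one synthetic drying curve.

    The ground-truth moisture trajectory is X(t) = MR(t) (X0 - Xe) + Xe with
    MR from the Crank slab series (``model="crank_series"``, ``n_terms``
    terms; 1 reproduces the one-term log-linear model exactly) or from a
    full transport-solver run (``model="solver"``); additive Gaussian noise
    of SD ``noise_sd`` (dry-basis units) is then applied and the result
    clipped at zero.
    """

    deff: float  # m^2/s
    air_temperature: float = 50.0  # deg C, metadata + solver air state
    thickness: float = 0.005  # m
    x0: float = 3.5657  # kg/kg db
    xe: float = 0.01  # kg/kg db
    times: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 6900.0, 30)
    )  # s
    noise_sd: float = 0.0  # kg/kg db
    model: Literal["crank_series", "solver"] = "crank_series"
    n_terms: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.deff <= 0 or self.thickness <= 0:
            raise ValueError("deff and thickness must be positive")
        if not self.x0 > self.xe >= 0:
            raise ValueError("need x0 > xe >= 0")


def generate_drying_curve(spec: CurveGenSpec) -> DryingCurve:
    """Synthesize a falling-rate drying curve per ``spec`` (seeded)."""
    if spec.model == "crank_series":
        mr = np.asarray(
            crank_mr(spec.deff, spec.thickness, spec.times, n_terms=spec.n_terms)
        )
    elif spec.model == "solver":
        from .solver import dirichlet_limit_config, simulate

        cfg = dirichlet_limit_config(
            spec.air_temperature,
            deff=spec.deff,
            duration=float(spec.times[-1]) if len(spec.times) else 0.0,
        )
        res = simulate(cfg)
        mr = np.interp(spec.times, res.times, res.moisture_ratio())
    else:
        raise ValueError(f"unknown generator model {spec.model!r}")

    x = mr * (spec.x0 - spec.xe) + spec.xe
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.noise_sd, size=x.shape)
    x = np.clip(x, 0.0, None)
    return DryingCurve(
        times=spec.times,
        moisture=x,
        air_temperature=spec.air_temperature,
        thickness_L=spec.thickness,
        label=f"synthetic {spec.model} @ {spec.air_temperature} degC",
    )


def generate_temperature_series(
    T0: float,
    T_inf: float,
    time_constant: float,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential-approach foam temperature trace (seeded).

    T(t) = T_inf - (T_inf - T0) exp(-t / tau) + noise.  ``time_constant=0``
    gives the instantaneous-equilibration limit T(t) = T_inf.
    Returns ``(times, temperatures)``.
    """
    if time_constant < 0 or noise_sd < 0:
        raise ValueError("time_constant and noise_sd must be nonnegative")
    if times is None:
        times = np.linspace(0.0, 6900.0, 231)
    times = np.asarray(times, dtype=float)
    if time_constant == 0:
        temp = np.full_like(times, T_inf)
    else:
        temp = T_inf - (T_inf - T0) * np.exp(-times / time_constant)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        temp = temp + rng.normal(0.0, noise_sd, size=temp.shape)
    return times, temp


@dataclass(frozen=True)
class ReplicateSpec:
    """Recipe for a replicate measurement table.

    ``means``/``sds`` map quantity name -> true mean / replicate SD (per
    group, e.g. air temperature).  Default: the study-condition powder
    quality tables with triplicate replicates.
    """

    means: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: TABLE_QUALITY_MEANS
    )
    sds: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: TABLE_QUALITY_SDS
    )
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        for group, row in self.sds.items():
            for key, sd in row.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {key} in group {group}")


def generate_replicates(spec: ReplicateSpec) -> pd.DataFrame:
    """Gaussian replicate table, clipped to physical ranges (seeded).

    One row per (group, replicate); columns are the quantities.  Clipping
    introduces a slight mean bias when an SD is comparable to the distance
    to a bound; with the study-condition SDs this is negligible.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in spec.means:
        mean_row = spec.means[group]
        sd_row = spec.sds.get(group, {})
        for rep in range(spec.n_replicates):
            row: dict = {"group": group, "replicate": rep + 1}
            for key, mu in mean_row.items():
                sd = sd_row.get(key, 0.0)
                val = float(rng.normal(mu, sd)) if sd > 0 else float(mu)
                lo, hi = _CLIP_BOUNDS.get(key, (None, None))
                if lo is not None:
                    val = max(val, lo)
                if hi is not None:
                    val = min(val, hi)
                row[key] = val
            rows.append(row)
    return pd.DataFrame(rows)
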