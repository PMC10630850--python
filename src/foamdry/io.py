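"""File I/O and report assembly: CSV dialects, JSON reports, manifests.

Drying curves travel as two-column CSV (``time_s,moisture_db``), one file
per air temperature, with temperature and thickness supplied via config.
Every writer drops a JSON manifest next to its outputs (inputs, resolved
configuration, package version, seed) sufficient to regenerate them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .kinetics import ArrheniusFit, DryingCurve, KineticsFit
from .solver import SimulationResult

CURVE_HEADER = ["time_s", "moisture_db"]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_drying_curve(
    path: str | Path,
    air_temperature: float,
    thickness_L: float = 0.005,
    label: str | None = None,
) -> DryingCurve:
    """Read a ``time_s,moisture_db`` CSV into a DryingCurve."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"drying-curve file not found: {path}")
    df = pd.read_csv(path)
    if list(df.columns[:2]) != CURVE_HEADER:
        raise ValueError(
            f"{path}: expected header {','.join(CURVE_HEADER)}, "
            f"got {','.join(map(str, df.columns[:2]))}"
        )
    return DryingCurve(
        times=df["time_s"].to_numpy(float),
        moisture=df["moisture_db"].to_numpy(float),
        air_temperature=air_temperature,
        thickness_L=thickness_L,
        label=label or path.stem,
    )


def write_drying_curve(curve: DryingCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": curve.times, "moisture_db": curve.moisture}
    ).to_csv(path, index=False)


def write_manifest(
    path: str | Path, *, inputs: Any, config: Any, seed: int | None = None
) -> None:
    from . import __version__

    payload = {
        "package": "foamdry",
        "version": __version__,
        "seed": seed,
        "inputs": _jsonable(inputs),
        "resolved_config": _jsonable(config),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_kinetics_report(
    out_dir: str | Path,
    fits: dict[float, KineticsFit],
    arrhenius: ArrheniusFit | None,
) -> tuple[Path, Path]:
    """Per-temperature fit CSV plus a JSON summary with the Arrhenius block."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "air_temperature_C": T,
            "deff_m2_s": f.deff,
            "slope_1_s": f.slope,
            "intercept": f.intercept,
            "r_squared": f.r_squared,
            "n_points_used": f.n_points_used,
        }
        for T, f in sorted(fits.items())
    ]
    csv_path = out_dir / "kinetics_fits.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    summary = {"fits": rows}
    if arrhenius is not None:
        summary["arrhenius"] = {
            "ea_J_mol": arrhenius.ea,
            "ea_kJ_mol": arrhenius.ea / 1000.0,
            "d0_m2_s": arrhenius.d0,
            "slope_k2_K": arrhenius.slope_k2,
            "r_squared": arrhenius.r_squared,
        }
    json_path = out_dir / "kinetics_summary.json"
    json_path.write_text(json.dumps(_jsonable(summary), indent=2) + "\n")
    return csv_path, json_path


def write_simulation_report(out_dir: str | Path, result: SimulationResult) -> Path:
    """Long-format snapshot CSV, summary-series CSV, and a JSON run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    recs = []
    if result.radii is None:
        for ti, t in enumerate(result.times):
            for xi, pos in enumerate(result.positions):
                recs.append(
                    (t, pos, result.temperature[ti, xi], result.moisture[ti, xi])
                )
        snap = pd.DataFrame(
            recs, columns=["time_s", "position_m", "temperature_C", "moisture_db"]
        )
    else:
        for ti, t in enumerate(result.times):
            for ri, rad in enumerate(result.radii):
                for xi, pos in enumerate(result.positions):
                    recs.append(
                        (
                            t, pos, rad,
                            result.temperature[ti, ri, xi],
                            result.moisture[ti, ri, xi],
                        )
                    )
        snap = pd.DataFrame(
            recs,
            columns=["time_s", "position_m", "radius_m", "temperature_C", "moisture_db"],
        )
    snap.to_csv(out_dir / "snapshots.csv", index=False)

    pd.DataFrame(
        {
            "time_s": result.times,
            "average_moisture_db": result.average_moisture,
            "average_temperature_C": result.average_temperature,
            "surface_moisture_db": result.surface_moisture,
            "bottom_moisture_db": result.bottom_moisture,
        }
    ).to_csv(out_dir / "summary.csv", index=False)

    report = {
        "transfer_coefficients": result.coefficients.as_dict(),
        "mass_balance_residual": result.mass_balance_residual,
        "evaporated_mass_kg_m2": result.evaporated_mass,
        "termination_time_s": result.termination_time,
        "termination_reason": result.termination_reason,
        "resolved_config": result.manifest()["config"],
    }
    path = out_dir / "run_report.json"
    path.write_text(json.dumps(_jsonable(report), indent=2) + "\n")
    return path
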