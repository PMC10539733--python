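"""CSV/JSON readers and writers plus the packaged reference tables.

Packaged fixtures (``fpro/data``):

* ``fluoroproline_geometry.csv`` — F–H distances and ¹⁹F CSA tensor
  summaries for the four fluoroproline ring conformers;
* ``peptide_shifts.csv`` — ¹H/¹³C assignments of the MpRS and MpSR
  peptides with the printed Cβ−Cγ and ΔCα columns;
* ``scalar_couplings.csv`` — ring ³J couplings of the four peptide FPro
  sites and the free amino-acid references;
* ``measured_relaxation.csv`` — measured R1, R2, NOE, ρ and σ per signal.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .binding import TitrationSeries
from .relaxation import SpinSystemGeometry
from .relaxfit import DecaySeries
from .reporters import COUPLING_NAMES, CouplingSet

__all__ = [
    "SchemaError",
    "fixture_path",
    "load_geometry_table",
    "load_shift_table",
    "load_coupling_table",
    "load_measured_relaxation",
    "read_geometry_csv",
    "read_series_csv",
    "write_series_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_couplings_csv",
    "write_result_json",
]

GEOMETRY_COLUMNS = [
    "label",
    "r_HG",
    "r_HB2",
    "r_HB3",
    "r_HD2",
    "r_HD3",
    "delta_sigma_ppm",
    "eta",
    "anti_xy_ppm",
    "anti_xz_ppm",
    "anti_yz_ppm",
]


class SchemaError(ValueError):
    """A table is missing mandatory columns or mixes incompatible units."""


def fixture_path(name: str) -> Path:
    return Path(str(resources.files("fpro").joinpath("data", name)))


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


def read_geometry_csv(path: str | Path) -> list[SpinSystemGeometry]:
    df = pd.read_csv(path)
    _require(df, GEOMETRY_COLUMNS, f"geometry table {path}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                SpinSystemGeometry(
                    label=str(row["label"]),
                    proton_distances={
                        "HG": row["r_HG"],
                        "HB2": row["r_HB2"],
                        "HB3": row["r_HB3"],
                        "HD2": row["r_HD2"],
                        "HD3": row["r_HD3"],
                    },
                    delta_sigma=row["delta_sigma_ppm"],
                    eta_csa=row["eta"],
                    anti_xy=row["anti_xy_ppm"],
                    anti_xz=row["anti_xz_ppm"],
                    anti_yz=row["anti_yz_ppm"],
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"geometry table {path}, row {i + 2}: {exc}") from exc
    return out


def load_geometry_table() -> dict[str, SpinSystemGeometry]:
    """Packaged conformer geometries keyed by label."""
    return {g.label: g for g in read_geometry_csv(fixture_path("fluoroproline_geometry.csv"))}


def load_shift_table() -> pd.DataFrame:
    """Packaged peptide ¹H/¹³C shift assignments."""
    return pd.read_csv(fixture_path("peptide_shifts.csv"))


def load_coupling_table() -> dict[str, CouplingSet]:
    """Packaged ring scalar couplings keyed by site label."""
    return read_couplings_csv(fixture_path("scalar_couplings.csv"))


def load_measured_relaxation() -> pd.DataFrame:
    """Packaged measured relaxation rates and NOEs per ¹⁹F signal."""
    return pd.read_csv(fixture_path("measured_relaxation.csv"))


def read_couplings_csv(path: str | Path) -> dict[str, CouplingSet]:
    df = pd.read_csv(path)
    _require(df, ["label", *COUPLING_NAMES], f"coupling table {path}")
    out = {}
    for i, row in df.iterrows():
        vals = {
            n: (None if pd.isna(row[n]) else float(row[n])) for n in COUPLING_NAMES
        }
        try:
            out[str(row["label"])] = CouplingSet(**vals)
        except ValueError as exc:
            raise SchemaError(f"coupling table {path}, row {i + 2}: {exc}") from exc
    return out


def read_series_csv(path: str | Path, kind: str) -> DecaySeries:
    df = pd.read_csv(path)
    _require(df, ["time_s", "intensity"], f"series table {path}")
    errors = df["intensity_err"].to_numpy() if "intensity_err" in df.columns else None
    return DecaySeries(
        times=df["time_s"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        intensity_errors=errors,
        kind=kind,
    )


def write_series_csv(series: DecaySeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": series.times, "intensity": series.intensities})
    if series.intensity_errors is not None:
        df["intensity_err"] = series.intensity_errors
    df.to_csv(path, index=False)


def read_titration_csv(
    path: str | Path, spectrometer_mhz_19f: float | None = None
) -> TitrationSeries:
    df = pd.read_csv(path)
    _require(
        df,
        ["point_id", "peptide_total_uM", "sh3_total_uM", "signal", "shift_value", "shift_unit"],
        f"titration table {path}",
    )
    has_ppm_19f = (
        df["shift_value"].notna() & (df["shift_unit"] == "ppm")
    ).any()
    if has_ppm_19f and spectrometer_mhz_19f is None:
        raise SchemaError(
            f"titration table {path} carries ppm shifts but no 19F spectrometer "
            "frequency was given"
        )
    kwargs: dict[str, Any] = {}
    if spectrometer_mhz_19f is not None:
        kwargs["spectrometer_mhz_19f"] = spectrometer_mhz_19f
    return TitrationSeries(data=df, **kwargs)


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    series.data.to_csv(path, index=False)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_result_json(
    path: str | Path, parameters: dict, uncertainties: dict | None = None, **extra: Any
) -> None:
    """Structured result file: parameters, uncertainties, provenance."""
    payload = {
        "parameters": _jsonify(parameters),
        "uncertainties": _jsonify(uncertainties or {}),
        "package_version": __version__,
    }
    payload.update({k: _jsonify(v) for k, v in extra.items()})
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))
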