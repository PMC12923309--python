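"""Readers and writers for the package's delimited-text formats.

All coefficients are stored internally in per-mm; property tables on disk
may declare per-cm via the ``unit`` column.  Impulse-response grids are
written as long-format CSV with a JSON sidecar carrying the scalar tallies
and the run configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .montecarlo import ImpulseResponse, SimulationGrid
from .optics import AbsorberSpectrum, Layer, OpticalProperties
from .photothermal import TemperatureTrace

__all__ = [
    "read_property_table",
    "write_property_table",
    "read_spectrum",
    "write_spectrum",
    "read_trace",
    "write_trace",
    "write_impulse_response",
    "read_impulse_response",
]

_PROP_COLUMNS = ["layer", "wavelength_nm", "mua", "mus", "unit", "g", "n", "thickness_mm"]


def read_property_table(path) -> dict[str, Layer]:
    """Optical-property table from CSV/TSV (columns: layer, wavelength_nm,
    mua, mus, unit(per_mm|per_cm), g, n, thickness_mm)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = set(_PROP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["unit"]) - {"per_mm", "per_cm"}
    if bad:
        raise ValueError(f"{path}: unknown unit values {sorted(bad)}")
    out: dict[str, Layer] = {}
    for name, group in df.groupby("layer", sort=False):
        props = {}
        for _, r in group.iterrows():
            scale = 0.1 if r["unit"] == "per_cm" else 1.0
            props[float(r["wavelength_nm"])] = OpticalProperties(
                mu_a=float(r["mua"]) * scale, mu_s=float(r["mus"]) * scale,
                g=float(r["g"]), n=float(r["n"]))
        out[str(name)] = Layer(name=str(name),
                               thickness=float(group["thickness_mm"].iloc[0]),
                               props=props)
    return out


def write_property_table(table: dict[str, Layer], path) -> None:
    rows = []
    for name, layer in table.items():
        for wl, p in sorted(layer.props.items()):
            rows.append({"layer": name, "wavelength_nm": wl, "mua": p.mu_a,
                         "mus": p.mu_s, "unit": "per_mm", "g": p.g, "n": p.n,
                         "thickness_mm": layer.thickness})
    pd.DataFrame(rows, columns=_PROP_COLUMNS).to_csv(path, index=False)


def read_spectrum(path, name: Optional[str] = None) -> AbsorberSpectrum:
    """Extinction spectrum from CSV (columns wavelength_nm, epsilon_per_M_per_cm)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("wavelength_nm", "epsilon_per_M_per_cm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return AbsorberSpectrum(name=name or path.stem,
                            wavelengths=df["wavelength_nm"].to_numpy(float),
                            epsilon=df["epsilon_per_M_per_cm"].to_numpy(float))


def write_spectrum(spectrum: AbsorberSpectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                  "epsilon_per_M_per_cm": spectrum.epsilon}).to_csv(path, index=False)


def read_trace(path, T_surr: Optional[float] = None) -> TemperatureTrace:
    """Temperature trace from CSV (time_s, temp_C, laser_on) with an optional
    JSON sidecar ``<stem>.json`` carrying metadata (T_surr_C, I_mW, ...)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise IOError(f"could not parse {path}: {exc}") from exc
    for col in ("time_s", "temp_C", "laser_on"):
        if col not in df.columns:
            raise ValueError(f"{path}, header line: missing column {col!r}")
    for col in ("time_s", "temp_C"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            # +2: 1-based lines plus the header row
            raise ValueError(
                f"{path}: unparseable {col!r} value on line {int(bad.idxmax()) + 2}")
        df[col] = coerced
    if T_surr is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            T_surr = json.loads(sidecar.read_text()).get("T_surr_C")
        if T_surr is None:
            T_surr = float(df["temp_C"].iloc[0])
    return TemperatureTrace(df["time_s"].to_numpy(float), df["temp_C"].to_numpy(float),
                            df["laser_on"].to_numpy(bool), float(T_surr))


def write_trace(trace: TemperatureTrace, path, metadata: Optional[dict] = None) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "temp_C": trace.temperatures,
                  "laser_on": trace.laser_on.astype(int)}).to_csv(path, index=False)
    meta = {"T_surr_C": trace.T_surr}
    if metadata:
        meta.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_impulse_response(imp: ImpulseResponse, csv_path, sidecar_path=None) -> None:
    """Long-format grid CSV (ir, iz, r_mm, z_mm, A_per_mm3, Phi_per_mm2) plus
    a JSON sidecar with the scalar tallies and run configuration."""
    csv_path = Path(csv_path)
    nr, nz = imp.A_rz.shape
    ir, iz = np.meshgrid(np.arange(nr), np.arange(nz), indexing="ij")
    df = pd.DataFrame({
        "ir": ir.ravel(), "iz": iz.ravel(),
        "r_mm": imp.r_centers[ir.ravel()], "z_mm": imp.z_centers[iz.ravel()],
        "A_per_mm3": imp.A_rz.ravel(), "Phi_per_mm2": imp.Phi_rz.ravel(),
    })
    df.to_csv(csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "R_sp": imp.R_sp, "R_d": imp.R_d, "A_total": imp.A_total, "T_t": imp.T_t,
        "n_photons": imp.n_photons, "seed": imp.seed, "wavelength_nm": imp.wavelength,
        "overflow_r": imp.overflow_r, "overflow_z": imp.overflow_z,
        "grid": {"dz": imp.grid.dz, "dr": imp.grid.dr,
                 "nz": imp.grid.nz, "nr": imp.grid.nr},
    }, indent=2))


def read_impulse_response(csv_path, sidecar_path=None) -> ImpulseResponse:
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    g = meta["grid"]
    grid = SimulationGrid(dz=g["dz"], dr=g["dr"], nz=g["nz"], nr=g["nr"])
    df = pd.read_csv(csv_path)
    A = np.zeros((grid.nr, grid.nz))
    Phi = np.zeros((grid.nr, grid.nz))
    A[df["ir"], df["iz"]] = df["A_per_mm3"]
    Phi[df["ir"], df["iz"]] = df["Phi_per_mm2"]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_a_z = np.where(Phi.max(axis=0) > 0,
                          np.nanmax(np.where(Phi > 0, A / np.where(Phi > 0, Phi, 1.0), 0.0), axis=0),
                          0.0)
    return ImpulseResponse(A_rz=A, Phi_rz=Phi, mu_a_z=mu_a_z, grid=grid,
                           R_sp=meta["R_sp"], R_d=meta["R_d"], T_t=meta["T_t"],
                           A_total=meta["A_total"], n_photons=meta["n_photons"],
                           seed=meta["seed"], wavelength=meta.get("wavelength_nm"),
                           overflow_r=meta.get("overflow_r", 0.0),
                           overflow_z=meta.get("overflow_z", 0.0))
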