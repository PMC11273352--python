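"""File formats: I-V sweep CSVs, defect-profile CSVs, TIFF stacks, catalogs.

CSV dialects (header required, '.' decimal separator):

* I-V sweeps: columns ``voltage_V, current_A``.
* Defect profiles: columns ``xi, dG_kJ_per_mol, flux_ions_per_s``.
* Domain catalogs: ``frame, x, y, area_um2, mean_potential_V``.

Image stacks are read from any TIFF tifffile understands and written as
32-bit float TIFF (potential maps) alongside JSON acquisition metadata.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .electro import IVFit, IVRecord
from .imaging import DomainRecord
from .needle import DefectProfiles

__all__ = [
    "read_iv_csv",
    "write_iv_csv",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_stack",
    "write_stack",
    "write_domain_catalog",
    "iv_fit_report",
    "write_json",
]

_IV_COLUMNS = ["voltage_V", "current_A"]
_PROFILE_COLUMNS = ["xi", "dG_kJ_per_mol", "flux_ions_per_s"]


def read_iv_csv(path) -> IVRecord:
    """Read one I-V sweep; raises with the file name and offending row on bad data."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _IV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in _IV_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise ValueError(f"{path}: non-numeric value in column '{col}' at row {row}")
    df = df.dropna()
    return IVRecord(
        voltages=df["voltage_V"].to_numpy(float),
        currents=df["current_A"].to_numpy(float),
        label=path.stem,
    )


def write_iv_csv(path, iv: IVRecord) -> None:
    pd.DataFrame({"voltage_V": iv.voltages, "current_A": iv.currents}).to_csv(
        path, index=False
    )


def read_profiles_csv(path, voltage: float = 0.3) -> DefectProfiles:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return DefectProfiles(
        xi=df["xi"].to_numpy(float),
        dG=df["dG_kJ_per_mol"].to_numpy(float),
        flux=df["flux_ions_per_s"].to_numpy(float),
        voltage=voltage,
    )


def write_profiles_csv(path, profiles: DefectProfiles) -> None:
    pd.DataFrame(
        {
            "xi": profiles.xi,
            "dG_kJ_per_mol": profiles.dG,
            "flux_ions_per_s": profiles.flux,
        }
    ).to_csv(path, index=False)


def read_stack(path) -> np.ndarray:
    """Read a TIFF stack as a float array (frames, rows, cols)."""
    arr = tifffile.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D grayscale TIFF, got shape {arr.shape}")
    return arr


def write_stack(path, stack: np.ndarray) -> None:
    """Write a stack as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def write_domain_catalog(path, domains: Sequence[DomainRecord]) -> None:
    rows = [
        {
            "frame": d.frame,
            "x": d.centroid[1],
            "y": d.centroid[0],
            "area_um2": d.area_um2,
            "mean_potential_V": d.mean_potential,
        }
        for d in domains
    ]
    pd.DataFrame(rows, columns=["frame", "x", "y", "area_um2", "mean_potential_V"]).to_csv(
        path, index=False
    )


def iv_fit_report(fit: IVFit) -> dict:
    """JSON-ready summary of one I-V fit."""
    return {
        "G_S": fit.conductance,
        "Vm_V": None if fit.undefined_reversal else fit.reversal_potential,
        "specific_conductance_S_per_cm2": fit.specific_conductance,
        "r2": fit.r2,
        "extrapolated": fit.extrapolated,
        "label": fit.label,
    }


def write_json(path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, float) and not np.isfinite(o):
            return None
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default, allow_nan=True)
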