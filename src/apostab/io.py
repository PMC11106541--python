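"""Plate-reader table ingestion and report emission.

Readers accept comma-separated text with a required header, decimal points,
temperatures in °C (a ``sep`` override covers TSV exports); writers emit the
same dialects so generated fixtures round-trip through the readers.
Malformed rows are reported with their line numbers.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import ITCExperiment
from .meltcurves import MeltCurve
from .screening import AnsSpectrum

__all__ = [
    "read_melt_csv",
    "write_melt_csv",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_dose_csv",
    "read_itc_csv",
    "write_table",
]

_MELT_REQUIRED = ("well", "temperature_C", "fluorescence")
_MELT_OPTIONAL = ("protein", "compound", "conc_mM", "plate", "role")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def _float_or_nan(v):
    try:
        return float(v)
    except (TypeError, ValueError):
        return np.nan


def _check_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    # parse with Python's float() so written repr() values round-trip exactly
    for col in columns:
        coerced = df[col].map(_float_or_nan)
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line(s) {lines}")
        df[col] = coerced
    return df


def read_melt_csv(path, sep: str = ",") -> list[MeltCurve]:
    """Read a long-format melt export: one row per (well, temperature).

    Required columns ``well, temperature_C, fluorescence``; optional
    ``protein, compound, conc_mM, plate, role``.  Rows are sorted by
    temperature within each well.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, float_precision="round_trip")
    _require_columns(df, _MELT_REQUIRED, path)
    df = _check_numeric(df, ["temperature_C", "fluorescence"], path)
    if df[["temperature_C", "fluorescence"]].isna().any().any():
        raise ValueError(f"{path}: empty temperature/fluorescence cells")
    if "conc_mM" in df.columns:
        df = _check_numeric(df, ["conc_mM"], path)

    curves: list[MeltCurve] = []
    group_keys = ["well"] + [c for c in ("plate",) if c in df.columns]
    for _, g in df.groupby(group_keys, sort=True, dropna=False):
        g = g.sort_values("temperature_C")
        first = g.iloc[0]
        meta = {}
        if "plate" in g.columns and pd.notna(first.get("plate")):
            meta["plate"] = int(first["plate"])
        if "role" in g.columns and pd.notna(first.get("role")):
            meta["role"] = str(first["role"])
        curves.append(
            MeltCurve(
                well=str(first["well"]),
                temperatures=g["temperature_C"].to_numpy(),
                fluorescence=g["fluorescence"].to_numpy(),
                protein=str(first["protein"]) if "protein" in g.columns and pd.notna(first.get("protein")) else None,
                compound=str(first["compound"]) if "compound" in g.columns and pd.notna(first.get("compound")) else None,
                conc_mM=float(first["conc_mM"]) if "conc_mM" in g.columns and pd.notna(first.get("conc_mM")) else None,
                metadata=meta,
            )
        )
    return curves


def write_melt_csv(curves: list[MeltCurve], path, sep: str = ",") -> None:
    """Write melt curves in the long format :func:`read_melt_csv` consumes."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        w.writerow(list(_MELT_REQUIRED) + list(_MELT_OPTIONAL))
        for c in curves:
            plate = c.metadata.get("plate", "")
            role = c.metadata.get("role", "")
            for t, f in zip(c.temperatures, c.fluorescence):
                w.writerow([
                    c.well, repr(float(t)), repr(float(f)),
                    c.protein or "", c.compound or "",
                    "" if c.conc_mM is None else repr(float(c.conc_mM)),
                    plate, role,
                ])


def read_spectra_csv(path, sep: str = ",") -> list[AnsSpectrum]:
    """Read emission spectra: sample_id, wavelength_nm, intensity (+ optional protein, compound)."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, float_precision="round_trip")
    _require_columns(df, ("sample_id", "wavelength_nm", "intensity"), path)
    df = _check_numeric(df, ["wavelength_nm", "intensity"], path)
    out = []
    for sid, g in df.groupby("sample_id", sort=True):
        g = g.sort_values("wavelength_nm")
        first = g.iloc[0]
        out.append(
            AnsSpectrum(
                g["wavelength_nm"].to_numpy(), g["intensity"].to_numpy(),
                protein=str(first["protein"]) if "protein" in g.columns and pd.notna(first.get("protein")) else None,
                compound=str(first["compound"]) if "compound" in g.columns and pd.notna(first.get("compound")) else None,
                metadata={"sample_id": str(sid)},
            )
        )
    return out


def write_spectra_csv(spectra: list[AnsSpectrum], path, sep: str = ",") -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        w.writerow(["sample_id", "wavelength_nm", "intensity", "protein", "compound"])
        for i, s in enumerate(spectra):
            sid = s.metadata.get("sample_id", f"S{i + 1}")
            for lam, y in zip(s.wavelengths_nm, s.intensities):
                w.writerow([sid, repr(float(lam)), repr(float(y)), s.protein or "", s.compound or ""])


def read_dose_csv(path, sep: str = ","):
    """Read a Tm dose-response table: conc_mM, tm_c and optional sd."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, float_precision="round_trip")
    _require_columns(df, ("conc_mM", "tm_c"), path)
    cols = ["conc_mM", "tm_c"] + (["sd"] if "sd" in df.columns else [])
    df = _check_numeric(df, cols, path)
    return df.sort_values("conc_mM").reset_index(drop=True)


def read_itc_csv(sample_path, blank_path, cell_volume_ul: float,
                 cell_conc_uM: float, syringe_conc_mM: float, sep: str = ",") -> ITCExperiment:
    """Read paired sample/blank injection tables: injection_index, volume_ul, heat."""
    def load(p):
        df = pd.read_csv(p, sep=sep, dtype=str, float_precision="round_trip")
        _require_columns(df, ("injection_index", "volume_ul", "heat"), p)
        df = _check_numeric(df, ["injection_index", "volume_ul", "heat"], p)
        return df.sort_values("injection_index")

    s, b = load(Path(sample_path)), load(Path(blank_path))
    if len(s) != len(b) or not np.allclose(s["volume_ul"], b["volume_ul"]):
        raise ValueError("blank injection schedule does not match the sample schedule")
    return ITCExperiment(
        cell_volume_ul=cell_volume_ul,
        cell_conc_uM=cell_conc_uM,
        syringe_conc_mM=syringe_conc_mM,
        injection_volumes_ul=s["volume_ul"].to_numpy(),
        heats=s["heat"].to_numpy(),
        blank_heats=b["heat"].to_numpy(),
    )


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a report table: UTF-8, LF line endings, stable column order."""
    df.to_csv(Path(path), sep=sep, index=False, lineterminator="\n", encoding="utf-8")
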