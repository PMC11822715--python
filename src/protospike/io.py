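"""Readers and writers for the pipeline's on-disk formats.

All tabular data travels as CSV with unit-bearing headers (the source
figures mix ms/s and mV, so units must travel with the data), Boolean
tables as TSV, and results as JSON.  Every write is atomic
(write-temp-then-rename) so interrupted runs never leave truncated
files.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .boolgates import GATE_COLUMNS
from .dielectric import CapacitanceSpectrum
from .errors import FormatError
from .impedance import ImpedanceSpectrum
from .trace import VoltageTrace

TRACE_COLUMNS = ["time_s", "potential_mV"]
CAP_COLUMNS = ["frequency_Hz", "capacitance_F"]
IMP_COLUMNS = ["frequency_Hz", "Z_real_ohm", "Z_imag_ohm"]
MAG_COLUMNS = ["frequency_Hz", "Z_mod_ohm"]
SCHEMA_VERSION = 1


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    df = df[required].apply(pd.to_numeric, errors="coerce")
    n_nan = int(df.isna().any(axis=1).sum())
    if n_nan:
        warnings.warn(f"{path}: dropped {n_nan} row(s) with non-numeric or missing values",
                      stacklevel=2)
        df = df.dropna()
    if df.empty:
        raise FormatError(f"{path}: no usable data rows")
    return df


def read_trace(path) -> VoltageTrace:
    """Read a 2-column voltage trace CSV (time_s, potential_mV), sorted by time."""
    df = _read_table(path, TRACE_COLUMNS).sort_values("time_s")
    return VoltageTrace(df["time_s"].to_numpy(), df["potential_mV"].to_numpy())


def write_trace(trace: VoltageTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.time, "potential_mV": trace.potential})
    _atomic_write_text(path, df.to_csv(index=False, float_format="%.17g"))


def read_capacitance_spectrum(path) -> CapacitanceSpectrum:
    df = _read_table(path, CAP_COLUMNS).sort_values("frequency_Hz")
    return CapacitanceSpectrum(df["frequency_Hz"].to_numpy(),
                               df["capacitance_F"].to_numpy())


def write_capacitance_spectrum(spec: CapacitanceSpectrum, path) -> None:
    df = pd.DataFrame({"frequency_Hz": spec.frequency, "capacitance_F": spec.capacitance})
    _atomic_write_text(path, df.to_csv(index=False, float_format="%.17g"))


def read_impedance_spectrum(path) -> ImpedanceSpectrum:
    """Read a complex impedance CSV; a magnitude-only file is accepted
    (Z_mod_ohm becomes the real part with zero imaginary part)."""
    path = Path(path)
    try:
        df = _read_table(path, IMP_COLUMNS)
        z = df["Z_real_ohm"].to_numpy() + 1j * df["Z_imag_ohm"].to_numpy()
    except FormatError:
        df = _read_table(path, MAG_COLUMNS)
        z = df["Z_mod_ohm"].to_numpy().astype(complex)
    order = np.argsort(df["frequency_Hz"].to_numpy())
    return ImpedanceSpectrum(df["frequency_Hz"].to_numpy()[order], z[order])


def write_impedance_spectrum(spec: ImpedanceSpectrum, path) -> None:
    df = pd.DataFrame({
        "frequency_Hz": spec.frequency,
        "Z_real_ohm": spec.Z.real,
        "Z_imag_ohm": spec.Z.imag,
    })
    _atomic_write_text(path, df.to_csv(index=False, float_format="%.17g"))


def write_gate_table(df: pd.DataFrame, path) -> None:
    """Write a Boolean gate table as TSV in the canonical column order."""
    _atomic_write_text(path, df[GATE_COLUMNS].to_csv(index=False, sep="\t"))


def write_json(obj, path) -> None:
    """Schema-versioned, deterministic JSON dump (atomic)."""
    payload = {"schema_version": SCHEMA_VERSION, **obj} if isinstance(obj, dict) else obj
    _atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True,
                                        default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o).__name__}")
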