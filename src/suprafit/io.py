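"""CSV and YAML readers/writers for the documented tabular schemas.

All CSV files are comma-separated, UTF-8, ``.`` decimal, with optional
metadata carried in ``# key: value`` comment lines before the header row.
Units are encoded in the column names (``conc_M``, ``avg_tau_ns``, ...).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .isotherm import IsothermDataset
from .nmr_titration import TitrationDataset
from .photophysics import DecayHistogram
from .quenching import QuenchSeries
from .thermo import VanHoffDataset

__all__ = [
    "read_decay_csv", "write_decay_csv",
    "read_isotherm_csv", "write_isotherm_csv",
    "read_quench_csv", "write_quench_csv",
    "read_vant_hoff_csv", "write_vant_hoff_csv",
    "read_titration_csv", "write_titration_csv",
]


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _read_table(path, required_columns) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"{path}: file not found")
    meta = _read_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ConfigurationError(f"{path}: malformed CSV ({exc})") from exc
    for col in required_columns:
        if col not in df.columns:
            raise ConfigurationError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based numbering
            line_no = int(bad.idxmax()) + 2 + sum(1 for _ in meta)
            raise ConfigurationError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} near line {line_no}")
        df[col] = coerced
    return df, meta


def _write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    buf = _io.StringIO()
    for key, value in (meta or {}).items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


# decay histograms -----------------------------------------------------------

def read_decay_csv(path) -> DecayHistogram:
    """Read a ``time_ns,counts`` histogram (decay curve or IRF)."""
    df, _ = _read_table(path, ["time_ns", "counts"])
    return DecayHistogram(df["time_ns"].to_numpy(), df["counts"].to_numpy())


def write_decay_csv(path, histogram: DecayHistogram,
                    meta: dict | None = None) -> None:
    df = pd.DataFrame({"time_ns": histogram.channel_times,
                       "counts": histogram.counts})
    _write_table(path, df, meta)


# isotherm -------------------------------------------------------------------

def read_isotherm_csv(path) -> IsothermDataset:
    """Read ``conc_M,avg_tau_ns[,tau_sd_ns]`` with ``# temperature_C:``."""
    df, meta = _read_table(path, ["conc_M", "avg_tau_ns"])
    sd = df["tau_sd_ns"].to_numpy() if "tau_sd_ns" in df.columns else None
    temp = float(meta["temperature_C"]) if "temperature_C" in meta else None
    return IsothermDataset(df["conc_M"].to_numpy(),
                           df["avg_tau_ns"].to_numpy(),
                           lifetime_sd=sd, temperature_c=temp)


def write_isotherm_csv(path, data: IsothermDataset) -> None:
    df = pd.DataFrame({"conc_M": data.concentrations,
                       "avg_tau_ns": data.average_lifetimes})
    if data.lifetime_sd is not None:
        df["tau_sd_ns"] = data.lifetime_sd
    meta = {}
    if data.temperature_c is not None:
        meta["temperature_C"] = data.temperature_c
    _write_table(path, df, meta)


# quenching ------------------------------------------------------------------

def read_quench_csv(path) -> QuenchSeries:
    df, _ = _read_table(path, ["q_conc_M", "avg_tau_ns"])
    return QuenchSeries(df["q_conc_M"].to_numpy(), df["avg_tau_ns"].to_numpy())


def write_quench_csv(path, series: QuenchSeries) -> None:
    _write_table(path, pd.DataFrame({
        "q_conc_M": series.quencher_concentrations,
        "avg_tau_ns": series.average_lifetimes}))


# van't Hoff -----------------------------------------------------------------

def read_vant_hoff_csv(path) -> VanHoffDataset:
    df, _ = _read_table(path, ["temp_C", "K"])
    sd = df["K_sd"].to_numpy() if "K_sd" in df.columns else None
    return VanHoffDataset(df["temp_C"].to_numpy(), df["K"].to_numpy(), k_sd=sd)


def write_vant_hoff_csv(path, data: VanHoffDataset) -> None:
    df = pd.DataFrame({"temp_C": data.temperatures_c, "K": data.k_values})
    if data.k_sd is not None:
        df["K_sd"] = data.k_sd
    _write_table(path, df)


# NMR titration --------------------------------------------------------------

def read_titration_csv(path) -> TitrationDataset:
    """Read ``guest_total_M,shift_ppm_<label>...`` with ``# host_total_M:``."""
    df, meta = _read_table(path, ["guest_total_M"])
    shift_cols = [c for c in df.columns if c.startswith("shift_ppm_")]
    if not shift_cols:
        raise ConfigurationError(
            f"{path}: no shift_ppm_<label> columns found")
    if "host_total_M" not in meta:
        raise ConfigurationError(
            f"{path}: missing '# host_total_M:' metadata line")
    labels = tuple(c.removeprefix("shift_ppm_") for c in shift_cols)
    return TitrationDataset(
        host_total=float(meta["host_total_M"]),
        guest_totals=df["guest_total_M"].to_numpy(),
        shifts=df[shift_cols].to_numpy(),
        labels=labels)


def write_titration_csv(path, data: TitrationDataset) -> None:
    df = pd.DataFrame({"guest_total_M": data.guest_totals})
    for j, label in enumerate(data.labels):
        df[f"shift_ppm_{label}"] = data.shifts[:, j]
    _write_table(path, df, {"host_total_M": repr(data.host_total)})
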