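"""Delimited-text I/O for traces, series, sample metadata and calibration tables.

All artifact formats are plain CSV with fixed headers so they diff and
version cleanly:

* trace files: ``time_ps,amplitude`` (one file per trace);
* temperature series: ``temperature_K,alpha_per_cm[,se_per_cm]``;
* sample metadata: ``sample_id,thickness_mm,mass_before_mg,mass_after_mg,
  storage_rh,tg_K`` (thickness on disk is mm, converted to cm on read with a
  logged conversion);
* calibration tables: ``tg_K,moisture_percent``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extraction import TemperatureSeries, TimeDomainTrace
from .hydration import CalibrationCurve, SampleRecord

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def write_trace(path: Path | str, trace: TimeDomainTrace) -> None:
    pd.DataFrame(
        {"time_ps": trace.time_ps, "amplitude": trace.amplitude}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace(path: Path | str, temperature_K: float, role: str) -> TimeDomainTrace:
    df = pd.read_csv(path)
    missing = {"time_ps", "amplitude"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return TimeDomainTrace(
        df["time_ps"].to_numpy(float), df["amplitude"].to_numpy(float),
        temperature_K, role,
    )


def write_series(path: Path | str, series: TemperatureSeries) -> None:
    data = {
        "temperature_K": series.temperature_K,
        "alpha_per_cm": series.alpha_percm,
    }
    if series.se_percm is not None:
        data["se_per_cm"] = series.se_percm
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series(
    path: Path | str, probe_frequency_thz: float = 1.0, sample_id: str = ""
) -> TemperatureSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    df = pd.read_csv(path)
    missing = {"temperature_K", "alpha_per_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    se = df["se_per_cm"].to_numpy(float) if "se_per_cm" in df.columns else None
    return TemperatureSeries(
        temperature_K=df["temperature_K"].to_numpy(float),
        alpha_percm=df["alpha_per_cm"].to_numpy(float),
        probe_frequency_thz=probe_frequency_thz,
        sample_id=sample_id or path.stem,
        se_percm=se,
    )


def write_sample_table(path: Path | str, samples: Sequence[dict]) -> None:
    rows = [
        {
            "sample_id": s["sample_id"],
            "thickness_mm": 10.0 * s["thickness_cm"],
            "mass_before_mg": s["mass_before_mg"],
            "mass_after_mg": s["mass_after_mg"],
            "storage_rh": s["storage_rh_percent"],
            "tg_K": s.get("tg_K", ""),
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sample_table(path: Path | str) -> list[SampleRecord]:
    df = pd.read_csv(path)
    required = {"sample_id", "thickness_mm", "mass_before_mg", "mass_after_mg", "storage_rh"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    logger.info("converting thickness from mm (on disk) to cm (internal) for %s", path)
    records = []
    for _, row in df.iterrows():
        tg = row.get("tg_K")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                thickness_cm=float(row["thickness_mm"]) / 10.0,
                mass_before_mg=float(row["mass_before_mg"]),
                mass_after_mg=float(row["mass_after_mg"]),
                storage_rh_percent=float(row["storage_rh"]),
                tg_K=float(tg) if tg is not None and np.isfinite(float(tg)) else None,
            )
        )
    return records


def write_calibration_table(
    path: Path | str, tg_K: Sequence[float], moisture_percent: Sequence[float]
) -> None:
    pd.DataFrame({"tg_K": tg_K, "moisture_percent": moisture_percent}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_calibration_table(path: Path | str) -> CalibrationCurve:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"calibration table not found: {path}")
    df = pd.read_csv(path)
    missing = {"tg_K", "moisture_percent"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return CalibrationCurve(
        tg_K=df["tg_K"].to_numpy(float),
        moisture_percent=df["moisture_percent"].to_numpy(float),
    )
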