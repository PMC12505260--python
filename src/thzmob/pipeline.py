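"""Config-driven orchestration of the full analysis.

A single study config names the sample manifest, the per-sample breakpoints
and rate windows (the reproducible record of choices an analyst would make
visually), the probe frequency and the calibration table.  ``run_pipeline``
executes hydration bookkeeping, piecewise thermal fitting and rate
decomposition for every sample, fits the study-level low-temperature
absorption versus uptake line, and writes a machine-readable report plus
per-sample intermediates from which the report can be regenerated
byte-identically.

Every numeric report field carries a unit suffix in its name
(``_K``, ``_percm``, ``_perK``, ``_percent``, ... or ``_unitless``); a schema
check rejects unitless numeric fields so no bare number ever leaves the
pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as tio
from .fitting import fit_piecewise
from .hydration import linear_correlation, moisture_from_tg, water_uptake_percent
from .rates import decompose_rates

logger = logging.getLogger(__name__)

_C_CM_PER_S = 2.99792458e10

_UNIT_SUFFIXES = (
    "_K", "_percm", "_perK", "_percent", "_percm_perK", "_Kpercm", "_cm",
    "_thz", "_mg", "_mm", "_unitless", "_x1e5_perK", "_percm_per_percent",
    "_cm2", "_n",
)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the sample and stage that raised it."""


def thz_to_wavenumber(nu_thz: float) -> float:
    """Convert a frequency in THz to a wavenumber in cm^-1 (nu / c)."""
    if nu_thz < 0:
        raise ValueError(f"frequency must be non-negative, got {nu_thz} THz")
    return nu_thz * 1e12 / _C_CM_PER_S


@dataclass
class SampleConfig:
    series_file: str
    breakpoints_K: list[float]
    evap_window_K: tuple[float, float]
    mob_window_K: Optional[tuple[float, float]] = None


@dataclass
class StudyConfig:
    sample_table: str
    calibration_table: str
    samples: dict[str, SampleConfig]
    output_dir: str = "results"
    probe_frequency_thz: float = 1.0
    seed: int = 0
    gated_correction: bool = True
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_file(cls, path: Path | str) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        samples = {
            sid: SampleConfig(
                series_file=s["series_file"],
                breakpoints_K=[float(b) for b in s["breakpoints_K"]],
                evap_window_K=tuple(s["evap_window_K"]),
                mob_window_K=tuple(s["mob_window_K"]) if s.get("mob_window_K") else None,
            )
            for sid, s in raw["samples"].items()
        }
        return cls(
            sample_table=raw["sample_table"],
            calibration_table=raw["calibration_table"],
            samples=samples,
            output_dir=raw.get("output_dir", "results"),
            probe_frequency_thz=float(raw.get("probe_frequency_thz", 1.0)),
            seed=int(raw.get("seed", 0)),
            gated_correction=bool(raw.get("gated_correction", True)),
            base_dir=path.parent,
        )

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


def _analyze_sample(config: StudyConfig, sid: str, record, calibration) -> dict:
    scfg = config.samples[sid]

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # annotate, never swallow
            raise PipelineError(f"sample {sid!r}, stage {name!r}: {exc}") from exc

    series = stage(
        "read_series",
        lambda: tio.read_series(
            config.resolve(scfg.series_file),
            probe_frequency_thz=config.probe_frequency_thz,
            sample_id=sid,
        ),
    )
    uptake = stage("water_uptake", lambda: water_uptake_percent(record))
    moisture = None
    if record.tg_K is not None:
        moisture = stage(
            "moisture_from_tg", lambda: moisture_from_tg(record.tg_K, calibration)
        )
    at80 = np.isclose(series.temperature_K, 80.0)
    alpha80 = float(series.alpha_percm[at80][0]) if np.any(at80) else None
    pw = stage(
        "piecewise_fit", lambda: fit_piecewise(series, scfg.breakpoints_K)
    )
    rates = stage(
        "rate_decomposition",
        lambda: decompose_rates(
            series,
            evap_window_K=scfg.evap_window_K,
            mob_window_K=scfg.mob_window_K,
            gated=config.gated_correction,
        ),
    )

    out: dict = {
        "storage_rh_percent": record.storage_rh_percent,
        "uptake_percent": uptake,
        "tg_K": record.tg_K,
        "moisture_from_tg_percent": moisture,
        "alpha_80K_percm": alpha80,
        "thickness_cm": record.thickness_cm,
        "t12_K": pw.t12_K,
        "t23_K": pw.t23_K,
        "k_evap_perK": rates.k_evap_perK,
        "k_mob_perK": rates.k_mob_perK,
        "k_evap_x1e5_perK": rates.k_evap_perK * 1e5,
        "k_mob_x1e5_perK": rates.k_mob_perK * 1e5,
        "segments": [
            {
                "A_percm_perK": s.A_percm_perK,
                "B_percm": s.B_percm,
                "C_Kpercm": s.C_Kpercm,
                "t_lo_K": s.t_range_K[0],
                "t_hi_K": s.t_range_K[1],
                "rss_cm2": s.rss,
                "points_n": s.n_points,
            }
            for s in pw.segments
        ],
        "evap_window_lo_K": rates.evap_window_K[0],
        "evap_window_hi_K": rates.evap_window_K[1],
        "mob_window_lo_K": rates.mob_window_K[0],
        "mob_window_hi_K": rates.mob_window_K[1],
    }
    return out


def build_report(per_sample: dict[str, dict], provenance: dict) -> dict:
    """Assemble the study report from per-sample intermediates (idempotent)."""
    pairs = [
        (s["uptake_percent"], s["alpha_80K_percm"])
        for s in per_sample.values()
        if s.get("alpha_80K_percm") is not None
    ]
    study: dict = {}
    if len(pairs) >= 3:
        x, y = zip(*pairs)
        slope, intercept, r2 = linear_correlation(x, y)
        study["alpha80_vs_uptake"] = {
            "slope_percm_per_percent": slope,
            "intercept_percm": intercept,
            "r_squared_unitless": r2,
            "points_n": len(pairs),
        }
    report = {"provenance": provenance, "samples": per_sample, "study": study}
    validate_report_units(report)
    return report


def validate_report_units(report: dict) -> None:
    """Reject numeric fields whose names carry no unit suffix."""

    def walk(node, path):
        if isinstance(node, dict):
            for key, value in node.items():
                walk(value, path + [key])
        elif isinstance(node, list):
            for item in node:
                walk(item, path)
        elif isinstance(node, (int, float)) and not isinstance(node, bool):
            key = path[-1] if path else ""
            if not any(key.endswith(suf) for suf in _UNIT_SUFFIXES):
                raise ValueError(
                    f"numeric report field {'.'.join(path)} lacks a unit suffix"
                )

    walk({"samples": report.get("samples", {}), "study": report.get("study", {})}, [])


def run_pipeline(config: StudyConfig) -> dict:
    """Run every stage for every sample and write report + intermediates.

    Deterministic given the config and seed.  Any stage error is re-raised as
    :class:`PipelineError` naming the failing sample and stage.
    """
    records = {
        r.sample_id: r for r in tio.read_sample_table(config.resolve(config.sample_table))
    }
    calibration = tio.read_calibration_table(config.resolve(config.calibration_table))
    missing = set(config.samples) - set(records)
    if missing:
        raise PipelineError(f"samples {sorted(missing)} missing from the sample table")

    per_sample = {
        sid: _analyze_sample(config, sid, records[sid], calibration)
        for sid in config.samples
    }

    provenance = {
        "config_sha256": _config_hash(config),
        "seed": str(config.seed),
        "package": "thzmob",
        "version": _package_version(),
    }
    report = build_report(per_sample, provenance)

    out_dir = config.resolve(config.output_dir)
    inter_dir = out_dir / "intermediates"
    inter_dir.mkdir(parents=True, exist_ok=True)
    for sid, data in per_sample.items():
        _dump_json(inter_dir / f"{sid}.json", data)
    _dump_json(out_dir / "report.json", report)
    logger.info("pipeline finished: %d samples -> %s", len(per_sample), out_dir)
    return report


def regenerate_report(intermediates_dir: Path | str, provenance: dict) -> dict:
    """Rebuild the study report from stored per-sample intermediates."""
    inter_dir = Path(intermediates_dir)
    per_sample = {
        p.stem: json.loads(p.read_text()) for p in sorted(inter_dir.glob("*.json"))
    }
    if not per_sample:
        raise PipelineError(f"no intermediates found in {inter_dir}")
    return build_report(per_sample, provenance)


def _config_hash(config: StudyConfig) -> str:
    payload = {
        "sample_table": config.sample_table,
        "calibration_table": config.calibration_table,
        "probe_frequency_thz": config.probe_frequency_thz,
        "seed": config.seed,
        "gated_correction": config.gated_correction,
        "samples": {
            sid: {
                "series_file": s.series_file,
                "breakpoints_K": s.breakpoints_K,
                "evap_window_K": list(s.evap_window_K),
                "mob_window_K": list(s.mob_window_K) if s.mob_window_K else None,
            }
            for sid, s in sorted(config.samples.items())
        },
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()


def _package_version() -> str:
    from . import __version__

    return __version__


def _dump_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
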