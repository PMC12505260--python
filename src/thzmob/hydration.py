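"""Hydration bookkeeping for humidity-conditioned samples.

Covers the four small calculations the study design needs: relative humidity
from a chamber/saturation pressure ratio, gravimetric water uptake from the
before/after conditioning masses, moisture content from a measured glass
transition temperature through a user-supplied Tg <-> moisture calibration
table (plasticization: more water, lower Tg), and the ordinary least-squares
line behind the low-temperature absorption versus uptake correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one conditioned disc."""

    sample_id: str
    thickness_cm: float
    mass_before_mg: float
    mass_after_mg: float
    storage_rh_percent: float
    tg_K: Optional[float] = None
    probe_alpha_80K_percm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mass_before_mg <= 0 or self.mass_after_mg <= 0:
            raise ValueError("masses must be positive")
        if self.thickness_cm <= 0:
            raise ValueError("thickness must be positive")
        if not 0.0 <= self.storage_rh_percent <= 100.0:
            raise ValueError("storage RH must be within [0, 100] %")


@dataclass(frozen=True)
class CalibrationCurve:
    """Tg <-> moisture calibration pairs (piecewise-linear interpolation).

    Higher moisture must correspond to lower Tg; the curve is never
    extrapolated because plasticization is visibly nonlinear outside the
    tabulated range.
    """

    tg_K: np.ndarray
    moisture_percent: np.ndarray

    def __post_init__(self) -> None:
        tg = np.asarray(self.tg_K, dtype=float)
        m = np.asarray(self.moisture_percent, dtype=float)
        order = np.argsort(tg)
        object.__setattr__(self, "tg_K", tg[order])
        object.__setattr__(self, "moisture_percent", m[order])
        if tg.ndim != 1 or m.shape != tg.shape or tg.size < 2:
            raise ValueError("calibration needs >= 2 (tg, moisture) pairs")
        if np.unique(tg).size != tg.size:
            raise ValueError("tg points must be strictly monotone")
        if np.any(np.diff(self.moisture_percent) >= 0):
            raise ValueError(
                "moisture must decrease as Tg increases (water plasticizes)"
            )


def estimate_rh_from_pressure(p_chamber_mbar: float, p_sat_mbar: float) -> float:
    """Relative humidity (%) from chamber pressure over saturation pressure."""
    if p_sat_mbar <= 0:
        raise ValueError("saturation pressure must be positive")
    if p_chamber_mbar < 0:
        raise ValueError("chamber pressure must be non-negative")
    if p_chamber_mbar > p_sat_mbar:
        raise ValueError(
            f"chamber pressure {p_chamber_mbar} mbar exceeds saturation "
            f"{p_sat_mbar} mbar (supersaturation is not modeled)"
        )
    # clamp: p == p_sat can round a hair above 100 in floating point
    return min(100.0 * p_chamber_mbar / p_sat_mbar, 100.0)


def water_uptake_percent(record: SampleRecord) -> float:
    """Gravimetric weight increase (%) over humidity conditioning."""
    if record.mass_before_mg <= 0:
        raise ValueError("mass before conditioning must be positive")
    uptake = 100.0 * (record.mass_after_mg - record.mass_before_mg) / record.mass_before_mg
    if uptake < 0:
        logger.warning(
            "sample %s lost mass during conditioning (%.3g %%)",
            record.sample_id, uptake,
        )
    return uptake


def moisture_from_tg(tg_K: float, curve: CalibrationCurve) -> float:
    """Moisture content (% w/w) from Tg via the calibration table (no extrapolation)."""
    lo, hi = float(curve.tg_K[0]), float(curve.tg_K[-1])
    if not lo <= tg_K <= hi:
        raise ValueError(
            f"Tg {tg_K} K outside the calibration range [{lo}, {hi}] K; "
            "extend the calibration table instead of extrapolating"
        )
    return float(np.interp(tg_K, curve.tg_K, curve.moisture_percent))


def linear_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept, r_squared).

    Constant y (zero total sum of squares) returns r^2 = 0 with a warning so
    degenerate fixtures keep flowing through the pipeline.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; slope is undefined")
    if np.ptp(y) == 0:
        logger.warning("constant y: total sum of squares is zero, returning r^2 = 0")
        return 0.0, float(y[0]), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
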