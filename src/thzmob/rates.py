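"""Evaporation / mobility rate decomposition of ln(alpha) versus temperature.

Above a hydration-dependent onset temperature, sorbed water leaves the disc
during the ramp and the measured absorption drops.  Assuming the polymer and
water contributions to ln(alpha) are approximately additive and that the
decline during evaporation follows pseudo-first-order kinetics in
temperature, the magnitude of the negative ln(alpha)-versus-T slope in a
user-chosen evaporation window defines the evaporation rate constant k_evap
(K^-1).  Subtracting this linear trend from ln(alpha) above the window onset
(gated by default; full-range subtraction is available) isolates the
underlying matrix contribution, and the slope of the corrected curve in a
mobility window is the mobility rate constant k_mob (K^-1).

Windows are explicit, reproducible inputs: the choice an analyst makes by eye
on a plot must enter the pipeline as configuration, not as a hidden
heuristic.  ``suggest_evaporation_window`` proposes the longest run of
consecutive negative finite differences as a starting point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .extraction import TemperatureSeries

logger = logging.getLogger(__name__)

_SLOPE_POSITIVE_TOL = 1e-12


@dataclass(frozen=True)
class LogSeries:
    """ln(alpha) versus temperature, with non-positive points masked out."""

    temperature_K: np.ndarray
    ln_alpha: np.ndarray
    sample_id: str = ""
    n_masked: int = 0


@dataclass(frozen=True)
class LinearFit:
    """One OLS line ln(alpha) = intercept + slope * T over a window."""

    slope_perK: float
    intercept: float
    window_K: tuple[float, float]
    rss: float
    n_points: int


@dataclass(frozen=True)
class RateResult:
    """Evaporation and mobility rate constants with their fit diagnostics."""

    k_evap_perK: float
    k_mob_perK: float
    evap_window_K: tuple[float, float]
    mob_window_K: tuple[float, float]
    evap_intercept: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_evap_perK < 0:
            raise ValueError("k_evap must be >= 0")


def log_series(series: TemperatureSeries) -> LogSeries:
    """Pointwise natural log; non-positive alpha points are masked with a warning."""
    positive = series.alpha_percm > 0
    n_masked = int((~positive).sum())
    if n_masked:
        logger.warning(
            "masking %d non-positive alpha point(s) before the log transform",
            n_masked,
        )
    t = series.temperature_K[positive]
    if t.size < 4:
        raise ValueError(
            f"only {t.size} positive alpha points remain; need >= 4"
        )
    return LogSeries(
        temperature_K=t,
        ln_alpha=np.log(series.alpha_percm[positive]),
        sample_id=series.sample_id,
        n_masked=n_masked,
    )


def _window_fit(ls: LogSeries, window_K: tuple[float, float], min_points: int) -> LinearFit:
    lo, hi = window_K
    if not lo < hi:
        raise ValueError(f"window ({lo}, {hi}) K is empty")
    mask = (ls.temperature_K >= lo) & (ls.temperature_K <= hi)
    t, y = ls.temperature_K[mask], ls.ln_alpha[mask]
    if t.size < min_points:
        raise ValueError(
            f"window ({lo}, {hi}) K holds {t.size} points; need >= {min_points}"
        )
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
    else:
        fit = stats.linregress(t, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    rss = float(np.sum((y - (intercept + slope * t)) ** 2))
    return LinearFit(slope, intercept, (float(lo), float(hi)), rss, int(t.size))


def fit_evaporation(ls: LogSeries, window_K: tuple[float, float]) -> LinearFit:
    """OLS line of ln(alpha) on T inside the evaporation window.

    The returned fit's ``-slope_perK`` is the evaporation rate constant;
    a positive in-window slope means the window does not show evaporation
    and raises with advice to adjust it.
    """
    fit = _window_fit(ls, window_K, min_points=3)
    if fit.slope_perK > _SLOPE_POSITIVE_TOL:
        raise ValueError(
            f"ln(alpha) slope in window {window_K} K is positive "
            f"({fit.slope_perK:.3g} /K): no evaporation decline there; "
            "adjust the window"
        )
    return fit


def correct_for_evaporation(
    ls: LogSeries, evap_fit: LinearFit, gated: bool = True
) -> LogSeries:
    """Remove the linear evaporation trend from ln(alpha).

    Adds ``k_evap * (T - T_onset)`` to ln(alpha), where the onset is the
    evaporation window's lower edge.  With ``gated=True`` (default) the
    correction applies only at and above the onset, leaving the low-
    temperature region -- where no water has left yet -- untouched;
    ``gated=False`` applies the literal full-range subtraction.
    """
    k_evap = max(-evap_fit.slope_perK, 0.0)
    t_ref = evap_fit.window_K[0]
    shift = k_evap * (ls.temperature_K - t_ref)
    if gated:
        shift = np.where(ls.temperature_K >= t_ref, shift, 0.0)
    return LogSeries(
        temperature_K=ls.temperature_K,
        ln_alpha=ls.ln_alpha + shift,
        sample_id=ls.sample_id,
        n_masked=ls.n_masked,
    )


def fit_mobility(
    ls_corrected: LogSeries, mob_window_K: Optional[tuple[float, float]] = None
) -> LinearFit:
    """OLS slope of the corrected ln(alpha) over the mobility window (default: full range)."""
    if mob_window_K is None:
        mob_window_K = (
            float(ls_corrected.temperature_K[0]),
            float(ls_corrected.temperature_K[-1]),
        )
    return _window_fit(ls_corrected, mob_window_K, min_points=4)


def suggest_evaporation_window(series: TemperatureSeries) -> tuple[float, float]:
    """Propose the longest run of consecutive negative ln(alpha) differences."""
    ls = log_series(series)
    neg = np.diff(ls.ln_alpha) < 0
    if not np.any(neg):
        raise ValueError("no decreasing run found; the series shows no evaporation")
    idx = np.flatnonzero(neg)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    best = max(runs, key=len)
    return (float(ls.temperature_K[best[0]]), float(ls.temperature_K[best[-1] + 1]))


def decompose_rates(
    series: TemperatureSeries,
    evap_window_K: tuple[float, float],
    mob_window_K: Optional[tuple[float, float]] = None,
    gated: bool = True,
) -> RateResult:
    """Full decomposition: log transform, evaporation fit, correction, mobility fit.

    Both rate constants are invariant to a positive rescaling of alpha (a
    constant shift of ln alpha), so the arbitrary amplitude units of the
    spectrometer drop out.
    """
    ls = log_series(series)
    evap = fit_evaporation(ls, evap_window_K)
    corrected = correct_for_evaporation(ls, evap, gated=gated)
    mob = fit_mobility(corrected, mob_window_K)
    return RateResult(
        k_evap_perK=max(-evap.slope_perK, 0.0),
        k_mob_perK=mob.slope_perK,
        evap_window_K=evap.window_K,
        mob_window_K=mob.window_K,
        evap_intercept=evap.intercept,
        diagnostics=dict(
            evap_rss=evap.rss,
            evap_n=evap.n_points,
            mob_rss=mob.rss,
            mob_n=mob.n_points,
            n_masked=ls.n_masked,
            gated=gated,
        ),
    )
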