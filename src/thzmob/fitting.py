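"""Piecewise empirical fitting of alpha(1 THz) versus temperature.

The temperature dependence of the terahertz absorption of an amorphous
polymer is described segment-wise by the empirical model

    alpha(T) = A*T + B + C/T

with a linear term A (cm^-1 K^-1), a constant offset B (cm^-1), and a
reciprocal curvature term C (cm^-1 K).  Fitting the model to distinct
temperature regions (low, intermediate, high) and intersecting adjacent
fitted curves yields the characteristic temperatures T12 and T23; T23 tracks
the calorimetric glass transition while T12 reflects sub-Tg dynamics.

Each segment fit is linear least squares in the basis {T, 1, 1/T} (weighted
by 1/se^2 when per-point standard errors are available), so noiseless model
data is recovered exactly.  Region boundaries can be supplied explicitly (the
reproducible analogue of the visual segmentation an analyst would do) or
chosen by exhaustive residual-sum-of-squares search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .extraction import TemperatureSeries

logger = logging.getLogger(__name__)

#: Two fitted curves are considered to genuinely intersect at T* only when
#: they agree there to better than this (cm^-1).
INTERSECTION_ALPHA_TOL = 1e-6


@dataclass(frozen=True)
class SegmentModel:
    """One fitted alpha = A*T + B + C/T segment."""

    A_percm_perK: float
    B_percm: float
    C_Kpercm: float
    t_range_K: tuple[float, float]
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        lo, hi = self.t_range_K
        if not lo < hi:
            raise ValueError(f"t_range ({lo}, {hi}) is empty")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")

    def alpha(self, temperature_K: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(temperature_K, dtype=float)
        out = self.A_percm_perK * t + self.B_percm + self.C_Kpercm / t
        return float(out) if out.ndim == 0 else out

    @property
    def midpoint_K(self) -> float:
        return 0.5 * (self.t_range_K[0] + self.t_range_K[1])


@dataclass(frozen=True)
class IntersectionResult:
    """Outcome of intersecting two fitted segments inside a bracket."""

    temperature_K: Optional[float]
    status: str  # "ok" | "no-root" | "coincident"
    bracket_K: tuple[float, float]
    roots_K: tuple[float, ...] = ()


@dataclass
class PiecewiseFit:
    """Ordered segment fits plus the characteristic intersection temperatures."""

    segments: list[SegmentModel]
    breakpoints_K: list[float]
    t12_K: Optional[float] = None
    t23_K: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        los = [s.t_range_K[0] for s in self.segments]
        if los != sorted(los):
            raise ValueError("segments must be ordered by temperature range")
        if self.t12_K is not None and self.t23_K is not None:
            if not self.t12_K < self.t23_K:
                raise ValueError("t12 must be below t23")


def _design(t: np.ndarray, fix_c_zero: bool) -> np.ndarray:
    cols = [t, np.ones_like(t)] if fix_c_zero else [t, np.ones_like(t), 1.0 / t]
    return np.column_stack(cols)


def fit_segment(
    series: TemperatureSeries,
    t_range_K: tuple[float, float],
    fix_c_zero: bool = False,
    weighted: bool = True,
    _closed_left: bool = True,
) -> SegmentModel:
    """Least-squares fit of alpha = A*T + B + C/T over a temperature range.

    The range is closed on both ends (``_closed_left=False`` makes the lower
    bound exclusive, used internally for contiguous region assignment).  When
    the series carries standard errors and ``weighted`` is true, points are
    weighted by 1/se^2.  Needs at least 4 in-range points (3 with
    ``fix_c_zero``), one more than the number of parameters.
    """
    lo, hi = t_range_K
    t_all = series.temperature_K
    mask = (t_all >= lo if _closed_left else t_all > lo) & (t_all <= hi)
    t = t_all[mask]
    y = series.alpha_percm[mask]
    n_par = 2 if fix_c_zero else 3
    if t.size < n_par + 1:
        raise ValueError(
            f"segment ({lo}, {hi}) K has {t.size} points; need >= {n_par + 1}"
        )
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive for the 1/T basis")
    if np.unique(t).size < n_par:
        raise ValueError(f"need >= {n_par} distinct temperatures in the segment")

    w = None
    if weighted and series.se_percm is not None:
        se = series.se_percm[mask]
        if np.all(np.isfinite(se)) and np.all(se > 0):
            w = 1.0 / se

    design = _design(t, fix_c_zero)
    rhs = y.copy()
    if w is not None:
        design = design * w[:, None]
        rhs = rhs * w
    # column scaling keeps the {T, 1, 1/T} basis well conditioned over
    # narrow high-temperature windows
    scale = np.linalg.norm(design, axis=0)
    scale[scale == 0] = 1.0
    coef, *_ = np.linalg.lstsq(design / scale, rhs, rcond=None)
    coef = coef / scale
    if fix_c_zero:
        a, b = coef
        c = 0.0
    else:
        a, b, c = coef
    resid = y - (a * t + b + c / t)
    if w is not None:
        rss = float(np.sum((w * resid) ** 2))
    else:
        rss = float(np.sum(resid**2))
    return SegmentModel(
        A_percm_perK=float(a),
        B_percm=float(b),
        C_Kpercm=float(c),
        t_range_K=(float(lo), float(hi)),
        rss=rss,
        n_points=int(t.size),
    )


def select_breakpoints(
    series: TemperatureSeries,
    n_segments: int = 3,
    grid_step_K: Optional[float] = None,
    min_points: int = 4,
) -> list[float]:
    """Exhaustive search for the breakpoints minimizing total segment RSS.

    Candidate breakpoints are the observed temperatures (or a regular grid of
    ``grid_step_K`` spanning the series).  A breakpoint temperature belongs to
    the segment below it.  Ties resolve deterministically to the smallest
    breakpoint temperatures, which matters only on degenerate flat objectives
    (e.g. a single generating model everywhere).
    """
    if n_segments not in (2, 3):
        raise ValueError("n_segments must be 2 or 3")
    t = series.temperature_K
    if t.size < n_segments * min_points:
        raise ValueError(
            f"series has {t.size} points; need >= {n_segments * min_points} "
            f"for {n_segments} segments of >= {min_points} points"
        )
    if grid_step_K is None:
        candidates = t
    else:
        candidates = np.arange(t[0], t[-1] + 0.5 * grid_step_K, grid_step_K)

    def n_in(lo: Optional[float], hi: Optional[float]) -> int:
        m = np.ones(t.size, dtype=bool)
        if lo is not None:
            m &= t > lo
        if hi is not None:
            m &= t <= hi
        return int(m.sum())

    def region_rss(lo: Optional[float], hi: Optional[float]) -> float:
        lo_eff = t[0] if lo is None else lo
        hi_eff = t[-1] if hi is None else hi
        seg = fit_segment(
            series, (lo_eff, hi_eff), _closed_left=(lo is None)
        )
        return seg.rss

    best: Optional[tuple[float, ...]] = None
    best_rss = np.inf
    # improvements below rounding level of the data are ties; ties keep the
    # earlier (smaller) breakpoints
    tie_tol = 1e-10 * float(np.sum(series.alpha_percm**2))
    interior = [c for c in candidates if t[0] < c < t[-1]]
    combos = (
        itertools.combinations(interior, 1)
        if n_segments == 2
        else itertools.combinations(interior, 2)
    )
    for bps in combos:
        bounds = [None, *bps, None]
        if any(
            n_in(bounds[i], bounds[i + 1]) < min_points for i in range(n_segments)
        ):
            continue
        try:
            total = sum(
                region_rss(bounds[i], bounds[i + 1]) for i in range(n_segments)
            )
        except ValueError:
            continue
        if total < best_rss - tie_tol:
            best_rss = total
            best = bps
    if best is None:
        raise ValueError("no admissible breakpoints satisfy min_points")
    return [float(b) for b in best]


def intersect_segments(
    seg_i: SegmentModel,
    seg_j: SegmentModel,
    bracket_K: tuple[float, float],
) -> IntersectionResult:
    """Locate the temperature where two fitted segments intersect.

    Setting the two A*T + B + C/T curves equal and multiplying by T gives the
    quadratic (dA)*T^2 + (dB)*T + dC = 0.  The unique real root inside the
    bracket is returned; no root yields an absent result with a diagnostic,
    and two in-bracket roots raise, demanding a narrower bracket rather than
    picking silently.
    """
    lo, hi = bracket_K
    if lo <= 0:
        raise ValueError("bracket must be at positive temperature")
    if not lo < hi:
        raise ValueError(f"bracket ({lo}, {hi}) is empty")
    da = seg_i.A_percm_perK - seg_j.A_percm_perK
    db = seg_i.B_percm - seg_j.B_percm
    dc = seg_i.C_Kpercm - seg_j.C_Kpercm
    # coincidence check on the curves themselves: two fits of the same
    # underlying model differ only at rounding level across the bracket
    probe = np.linspace(lo, hi, 17)
    gap_max = float(np.max(np.abs(seg_i.alpha(probe) - seg_j.alpha(probe))))
    alpha_scale = float(
        np.max(np.abs(np.concatenate([seg_i.alpha(probe), seg_j.alpha(probe), [1.0]])))
    )
    if gap_max < 1e-9 * alpha_scale:
        return IntersectionResult(None, "coincident", (lo, hi))
    t_scale = max(abs(lo), abs(hi))
    sa, sb = abs(da) * t_scale**2, abs(db) * t_scale
    scale = max(sa, sb, abs(dc))

    if sa <= 1e-14 * scale:
        roots = np.array([] if sb <= 1e-14 * scale else [-dc / db])
    else:
        disc = db * db - 4.0 * da * dc
        if disc < 0:
            roots = np.array([])
        else:
            sq = np.sqrt(disc)
            # numerically stable quadratic roots
            q = -0.5 * (db + np.copysign(sq, db))
            roots = np.array([q / da]) if q == 0 else np.array(
                [q / da, dc / q if q != 0 else np.nan]
            )
            roots = np.unique(roots[np.isfinite(roots)])
    inside = roots[(roots > lo) & (roots < hi)]
    if inside.size == 0:
        return IntersectionResult(None, "no-root", (lo, hi), tuple(float(r) for r in roots))
    if inside.size > 1:
        raise ValueError(
            f"two intersection roots {inside.tolist()} inside bracket ({lo}, {hi}) K; "
            "narrow the bracket"
        )
    t_star = float(inside[0])
    gap = abs(seg_i.alpha(t_star) - seg_j.alpha(t_star))
    if gap >= INTERSECTION_ALPHA_TOL:
        raise AssertionError(
            f"curves differ by {gap:.3g} cm^-1 at the computed intersection"
        )
    return IntersectionResult(t_star, "ok", (lo, hi), (t_star,))


def fit_piecewise(
    series: TemperatureSeries,
    breakpoints_K: Sequence[float],
    weighted: bool = True,
) -> PiecewiseFit:
    """Fit contiguous regions and intersect adjacent fitted curves.

    Regions are ``[T_min, b1], (b1, b2], ..., (b_last, T_max]``.  The
    intersection between adjacent segments is bracketed by the midpoints of
    the two regions it separates: a characteristic temperature must lie
    between the regions it divides.
    """
    bps = [float(b) for b in breakpoints_K]
    if bps != sorted(bps) or len(set(bps)) != len(bps):
        raise ValueError("breakpoints must be strictly increasing")
    t = series.temperature_K
    if bps and not (t[0] < bps[0] and bps[-1] < t[-1]):
        raise ValueError("breakpoints must lie strictly inside the series range")
    bounds = [float(t[0]), *bps, float(t[-1])]
    segments = [
        fit_segment(
            series,
            (bounds[i], bounds[i + 1]),
            weighted=weighted,
            _closed_left=(i == 0),
        )
        for i in range(len(bounds) - 1)
    ]
    diagnostics: dict = {}
    t12 = t23 = None
    if len(segments) >= 2:
        res = intersect_segments(
            segments[0], segments[1], (segments[0].midpoint_K, segments[1].midpoint_K)
        )
        t12 = res.temperature_K
        diagnostics["t12"] = res
    if len(segments) >= 3:
        res = intersect_segments(
            segments[1], segments[2], (segments[1].midpoint_K, segments[2].midpoint_K)
        )
        t23 = res.temperature_K
        diagnostics["t23"] = res
    return PiecewiseFit(
        segments=segments,
        breakpoints_K=bps,
        t12_K=t12,
        t23_K=t23,
        diagnostics=diagnostics,
    )
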