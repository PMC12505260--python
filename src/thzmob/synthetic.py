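"""Synthetic THz-TDS data with known ground truth.

Every downstream stage of the pipeline is validated against data generated
here: transmission pulse pairs through a slab with a prescribed absorption
spectrum and refractive index, and alpha(1 THz) versus temperature curves
with a known piecewise alpha = A*T + B + C/T structure, an evaporation
decline in log space, and a high-temperature recovery.

The packaged four-sample study fixture emulates melt-quenched PVP/VA discs
conditioned at 8.5, 54, 65 and 75% relative humidity: increasing hydration
raises the low-temperature absorption, lowers the glass transition, shifts
the characteristic intersection temperature T12 downward and speeds up both
the water-evaporation and mobility rates.  The generating constants are the
study's published per-sample values, so the fixture doubles as a ground-truth
oracle for end-to-end round trips.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .extraction import TemperatureSeries, TimeDomainTrace

logger = logging.getLogger(__name__)

#: speed of light in cm/ps
C_CM_PER_PS = 0.0299792458

#: Default measurement ramp: 80-420 K in 10 K steps.
DEFAULT_TEMPERATURES_K = np.arange(80.0, 421.0, 10.0)


# ---------------------------------------------------------------------------
# pulse pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlabOptics:
    """Optical properties of a homogeneous slab on a frequency grid."""

    frequency_thz: np.ndarray
    alpha_percm: np.ndarray
    n_index: np.ndarray
    thickness_cm: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_thz, dtype=float)
        a = np.asarray(self.alpha_percm, dtype=float)
        n = np.asarray(self.n_index, dtype=float)
        object.__setattr__(self, "frequency_thz", f)
        object.__setattr__(self, "alpha_percm", a)
        object.__setattr__(self, "n_index", n)
        if f.ndim != 1 or a.shape != f.shape or n.shape != f.shape:
            raise ValueError("alpha and n must be tabulated on the same 1-D grid")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("absorption coefficient must be non-negative")
        if np.any(n < 1):
            raise ValueError("refractive index must be >= 1")
        if self.thickness_cm <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness_cm} cm")


@dataclass(frozen=True)
class PulseShape:
    """Derivative-of-Gaussian excitation pulse.

    Chosen because it has an analytic spectrum, zero DC component, and a
    single bandwidth knob: the spectral amplitude is proportional to
    nu * exp(-2 pi^2 nu^2 width^2).
    """

    center_ps: float = 10.0
    width_ps: float = 0.15
    dt_ps: float = 0.05
    n_samples: int = 4096

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ps

    def amplitude(self) -> np.ndarray:
        t = self.time_grid() - self.center_ps
        w2 = self.width_ps**2
        a = -t / w2 * np.exp(-(t**2) / (2.0 * w2))
        return a / np.abs(a).max()

    def spectral_magnitude(self, nu_thz: np.ndarray) -> np.ndarray:
        """Analytic |FT| up to a constant factor, normalized to peak 1."""
        nu = np.asarray(nu_thz, dtype=float)
        mag = np.abs(nu) * np.exp(-2.0 * np.pi**2 * nu**2 * self.width_ps**2)
        peak = 1.0 / (2.0 * np.pi * self.width_ps)  # argmax of nu*exp(...)
        return mag / (peak * np.exp(-0.5))


def simulate_pulse_pair(
    optics: SlabOptics,
    pulse: Optional[PulseShape] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature_K: float = 80.0,
    bandwidth_floor: float = 1e-4,
    dynamic_range_band_thz: tuple[float, float] = (0.5, 2.5),
) -> tuple[TimeDomainTrace, TimeDomainTrace]:
    """Forward-model a reference/sample trace pair through a slab.

    In the frequency domain the sample field is the reference field times
    ``exp(-alpha d / 2) * exp(-i 2 pi nu (n - 1) d / c)``: amplitude
    attenuation from absorption and the group delay of propagation through
    the slab.  ``noise_sd`` adds Gaussian noise (as a fraction of the peak
    reference amplitude) to both traces; when noise is on, a raised-cosine
    dynamic-range roll-off outside ``dynamic_range_band_thz`` is applied
    identically to both signals, emulating the reduced out-of-band dynamic
    range of real systems without biasing the in-band amplitude ratio.

    Returns ``(reference, sample)``.  Identical seeds give identical traces.
    """
    pulse = pulse or PulseShape()
    nyquist = 0.5 / pulse.dt_ps
    f_top = float(optics.frequency_thz[-1])
    if f_top > nyquist:
        raise ValueError(
            f"optics grid frequency {f_top} THz exceeds the Nyquist frequency "
            f"{nyquist} THz of the pulse sampling"
        )
    rel = pulse.spectral_magnitude(optics.frequency_thz)
    weak = rel < bandwidth_floor
    if np.any(weak):
        nu_bad = float(optics.frequency_thz[np.argmax(weak)])
        raise ValueError(
            f"pulse bandwidth does not cover the optics grid: relative spectral "
            f"amplitude at {nu_bad} THz is below {bandwidth_floor}"
        )

    t = pulse.time_grid()
    ref = pulse.amplitude()
    freq = np.fft.rfftfreq(t.size, d=pulse.dt_ps)
    e_ref = np.fft.rfft(ref)

    alpha = np.interp(freq, optics.frequency_thz, optics.alpha_percm)
    n_idx = np.interp(freq, optics.frequency_thz, optics.n_index)
    delay_ps = (n_idx - 1.0) * optics.thickness_cm / C_CM_PER_PS
    transfer = np.exp(-alpha * optics.thickness_cm / 2.0) * np.exp(
        -2j * np.pi * freq * delay_ps
    )
    e_sam = e_ref * transfer

    if noise_sd > 0:
        lo, hi = dynamic_range_band_thz
        roll = _raised_cosine_band(freq, lo, hi, transition_thz=0.3, floor=0.05)
        e_ref = e_ref * roll
        e_sam = e_sam * roll

    ref_td = np.fft.irfft(e_ref, n=t.size)
    sam_td = np.fft.irfft(e_sam, n=t.size)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sd * np.abs(ref_td).max()
        ref_td = ref_td + rng.normal(0.0, scale, ref_td.shape)
        sam_td = sam_td + rng.normal(0.0, scale, sam_td.shape)

    reference = TimeDomainTrace(t, ref_td, temperature_K, "reference")
    sample = TimeDomainTrace(t, sam_td, temperature_K, "sample")
    return reference, sample


def _raised_cosine_band(
    freq: np.ndarray, lo: float, hi: float, transition_thz: float, floor: float
) -> np.ndarray:
    """Flat passband with smooth cosine shoulders decaying to ``floor``."""
    w = np.ones_like(freq)
    below = freq < lo
    above = freq > hi
    ramp_lo = np.clip((lo - freq[below]) / transition_thz, 0.0, 1.0)
    ramp_hi = np.clip((freq[above] - hi) / transition_thz, 0.0, 1.0)
    w[below] = floor + (1.0 - floor) * 0.5 * (1.0 + np.cos(np.pi * ramp_lo))
    w[above] = floor + (1.0 - floor) * 0.5 * (1.0 + np.cos(np.pi * ramp_hi))
    return w


# ---------------------------------------------------------------------------
# temperature series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesRecipe:
    """Ground truth for one alpha(1 THz) versus temperature curve.

    ``segments`` is an ordered, contiguous list of
    ``(t_lo_K, t_hi_K, A, B, C)`` tuples: within a segment the noiseless
    absorption is ``A*T + B + C/T`` (A in cm^-1 K^-1, B in cm^-1,
    C in cm^-1 K).  The first segment is closed on both ends; later segments
    cover ``(t_lo, t_hi]`` so a breakpoint temperature belongs to the segment
    below it.

    Water evaporation is applied multiplicatively in log space (the additive
    ln-alpha decomposition): for temperatures above ``evap_onset_K``,
    ln(alpha) additionally decreases at ``evap_log_slope_perK`` per K.  The
    onset switches on smoothly over ``evap_ramp_K`` (a softplus ramp; 0 gives
    an exact hinge), and the decline saturates at ``evap_end_K`` when given,
    emulating depletion of the finite water reservoir.
    """

    segments: tuple[tuple[float, float, float, float, float], ...]
    evap_onset_K: Optional[float] = None
    evap_log_slope_perK: float = 0.0
    evap_end_K: Optional[float] = None
    evap_ramp_K: float = 5.0
    noise_sd_percm: float = 0.0
    seed: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        segs = tuple(tuple(float(x) for x in s) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("recipe needs at least one segment")
        for lo, hi, *_ in segs:
            if not lo < hi:
                raise ValueError(f"segment range ({lo}, {hi}) K is empty")
        for (_, hi_prev, *_), (lo_next, *_) in zip(segs, segs[1:]):
            if hi_prev != lo_next:
                raise ValueError(
                    f"segments must be contiguous: {hi_prev} K != {lo_next} K"
                )
        if self.evap_log_slope_perK < 0:
            raise ValueError("evap_log_slope_perK must be >= 0")
        if self.noise_sd_percm < 0:
            raise ValueError("noise_sd_percm must be >= 0")
        if self.evap_ramp_K < 0:
            raise ValueError("evap_ramp_K must be >= 0")

    def base_alpha(self, temperature_K: np.ndarray) -> np.ndarray:
        """Noiseless segment model evaluated at the given temperatures."""
        t = np.asarray(temperature_K, dtype=float)
        lo0 = self.segments[0][0]
        hi_last = self.segments[-1][1]
        if np.any(t < lo0) or np.any(t > hi_last):
            raise ValueError(
                f"temperatures outside the recipe range [{lo0}, {hi_last}] K"
            )
        alpha = np.empty_like(t)
        for i, (lo, hi, a, b, c) in enumerate(self.segments):
            mask = (t >= lo) & (t <= hi) if i == 0 else (t > lo) & (t <= hi)
            alpha[mask] = a * t[mask] + b + c / t[mask]
        return alpha


def _evap_ramp(t: np.ndarray, onset: float, end: Optional[float], width: float) -> np.ndarray:
    """Integrated evaporation extent in K: ~max(0, T - onset), smoothed and saturating."""

    def softplus(x: np.ndarray) -> np.ndarray:
        if width == 0:
            return np.maximum(x, 0.0)
        return width * np.logaddexp(0.0, x / width)

    ramp = softplus(t - onset)
    if end is not None:
        ramp = ramp - softplus(t - end)
    return ramp


def simulate_temperature_series(
    recipe: SeriesRecipe,
    temperatures_K: Optional[np.ndarray] = None,
) -> TemperatureSeries:
    """Generate an alpha(1 THz, T) series from a recipe.

    Noiseless output is exactly the active segment's A*T + B + C/T below the
    evaporation onset, with the log-space evaporation decline folded in above
    it.  Any non-positive generated absorption raises before data leave this
    function.  Identical recipes (same seed) give identical series.
    """
    t = np.asarray(
        DEFAULT_TEMPERATURES_K if temperatures_K is None else temperatures_K,
        dtype=float,
    )
    alpha = recipe.base_alpha(t)
    if np.any(alpha <= 0):
        bad = float(t[np.argmax(alpha <= 0)])
        raise ValueError(f"recipe produces non-positive alpha at {bad} K")
    if recipe.evap_onset_K is not None and recipe.evap_log_slope_perK > 0:
        ramp = _evap_ramp(t, recipe.evap_onset_K, recipe.evap_end_K, recipe.evap_ramp_K)
        alpha = np.exp(np.log(alpha) - recipe.evap_log_slope_perK * ramp)
    if recipe.noise_sd_percm > 0:
        rng = np.random.default_rng(recipe.seed)
        alpha = alpha + rng.normal(0.0, recipe.noise_sd_percm, alpha.shape)
        if np.any(alpha <= 0):
            raise ValueError("noise drove alpha non-positive; reduce noise_sd")
    return TemperatureSeries(
        temperature_K=t,
        alpha_percm=alpha,
        probe_frequency_thz=1.0,
        sample_id=recipe.sample_id,
    )


def log_linear_rate_series(
    k_mob_perK: float,
    k_evap_perK: float,
    evap_onset_K: float,
    temperatures_K: Optional[np.ndarray] = None,
    ln_alpha0: float = 3.4,
    noise_sd_ln: float = 0.0,
    seed: int = 0,
    sample_id: str = "",
) -> TemperatureSeries:
    """Piecewise log-linear series for rate-decomposition round trips.

    Below the evaporation onset, ln(alpha) rises with the mobility slope
    ``k_mob_perK``; at and above it, ln(alpha) falls with slope exactly
    ``-k_evap_perK`` (the mobility contribution is suppressed while water
    dominates the signal change).  An evaporation-window fit above the onset
    therefore recovers ``k_evap_perK`` exactly, and a mobility fit below it
    recovers ``k_mob_perK`` exactly; optional Gaussian noise of ``noise_sd_ln``
    is added to ln(alpha).
    """
    t = np.asarray(
        DEFAULT_TEMPERATURES_K if temperatures_K is None else temperatures_K,
        dtype=float,
    )
    apex = ln_alpha0 + k_mob_perK * (evap_onset_K - t[0])
    ln_alpha = np.where(
        t < evap_onset_K,
        ln_alpha0 + k_mob_perK * (t - t[0]),
        apex - k_evap_perK * (t - evap_onset_K),
    )
    if noise_sd_ln > 0:
        rng = np.random.default_rng(seed)
        ln_alpha = ln_alpha + rng.normal(0.0, noise_sd_ln, ln_alpha.shape)
    return TemperatureSeries(
        temperature_K=t,
        alpha_percm=np.exp(ln_alpha),
        probe_frequency_thz=1.0,
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# the four-sample study fixture
# ---------------------------------------------------------------------------

#: Per-sample study conditions and published per-sample constants: storage
#: relative humidity, calorimetric glass transition, gravimetric water uptake,
#: moisture estimated through the Tg calibration, low-temperature segment
#: parameters (A, B, C) of alpha = A*T + B + C/T fitted over ~80-250 K,
#: characteristic intersection temperatures T12/T23, and the evaporation and
#: mobility rate constants of the ln(alpha) decomposition.
STUDY_SAMPLES: dict[str, dict] = {
    "pvpva1": dict(
        storage_rh_percent=8.5, tg_K=367.0, uptake_percent=0.0, moisture_percent=0.9,
        low_segment=(0.0241, 31.91, 0.0), t12_K=303.0, t23_K=361.0,
        k_evap_perK=1.86e-4, k_mob_perK=8.46e-4,
        breakpoints_K=(250.0, 380.0), evap_window_K=(360.0, 380.0),
        thickness_cm=0.05,
    ),
    "pvpva2": dict(
        storage_rh_percent=54.0, tg_K=314.0, uptake_percent=3.2, moisture_percent=11.2,
        low_segment=(0.0501, 27.63, 268.0), t12_K=298.0, t23_K=332.0,
        k_evap_perK=1.59e-3, k_mob_perK=2.63e-3,
        breakpoints_K=(250.0, 360.0), evap_window_K=(300.0, 360.0),
        thickness_cm=0.06,
    ),
    "pvpva3": dict(
        storage_rh_percent=65.0, tg_K=297.0, uptake_percent=7.4, moisture_percent=18.2,
        low_segment=(0.0508, 29.81, 233.0), t12_K=271.0, t23_K=298.0,
        k_evap_perK=3.11e-3, k_mob_perK=4.14e-3,
        breakpoints_K=(250.0, 340.0), evap_window_K=(280.0, 340.0),
        thickness_cm=0.07,
    ),
    "pvpva4": dict(
        storage_rh_percent=75.0, tg_K=275.0, uptake_percent=10.6, moisture_percent=28.5,
        low_segment=(0.0477, 32.59, 149.0), t12_K=252.0, t23_K=330.0,
        k_evap_perK=3.15e-3, k_mob_perK=4.14e-3,
        breakpoints_K=(250.0, 330.0), evap_window_K=(290.0, 330.0),
        thickness_cm=0.08,
    ),
}

_T_MIN_K = float(DEFAULT_TEMPERATURES_K[0])
_T_MAX_K = float(DEFAULT_TEMPERATURES_K[-1])
_NOMINAL_MASS_MG = 120.0


def study_recipe(sample_id: str, noise_sd_percm: float = 0.0, seed: int = 0) -> SeriesRecipe:
    """Build the three-segment generating recipe for one study sample.

    Construction rules (all anchored to the published per-sample constants):

    * low segment: the published (A, B, C) over [80, 250] K;
    * intermediate segment (C = 0): crosses the low segment exactly at T12 and
      has logarithmic slope -k_evap at the centre of the evaporation window,
      encoding the water-evaporation decline;
    * high segment (C = 0): crosses the intermediate segment exactly at T23
      and has logarithmic slope (k_mob - k_evap) at its centre, so that the
      evaporation-corrected log-slope of the post-evaporation region recovers
      the mobility rate k_mob.
    """
    spec = STUDY_SAMPLES[sample_id]
    a1, b1, c1 = spec["low_segment"]
    bp1, bp2 = spec["breakpoints_K"]
    t12, t23 = spec["t12_K"], spec["t23_K"]
    k_evap, k_mob = spec["k_evap_perK"], spec["k_mob_perK"]

    y12 = a1 * t12 + b1 + c1 / t12
    tc = 0.5 * (spec["evap_window_K"][0] + spec["evap_window_K"][1])
    yc = y12 / (1.0 + k_evap * (tc - t12))
    a2 = -k_evap * yc
    b2 = y12 - a2 * t12

    y23 = a2 * t23 + b2
    k_high = k_mob - k_evap
    th = 0.5 * (bp2 + _T_MAX_K)
    y3c = y23 / (1.0 - k_high * (th - t23))
    a3 = k_high * y3c
    b3 = y23 - a3 * t23

    return SeriesRecipe(
        segments=(
            (_T_MIN_K, bp1, a1, b1, c1),
            (bp1, bp2, a2, b2, 0.0),
            (bp2, _T_MAX_K, a3, b3, 0.0),
        ),
        noise_sd_percm=noise_sd_percm,
        seed=seed,
        sample_id=sample_id,
    )


def make_study_fixture(
    out_dir: Path | str,
    seed: int = 0,
    noise_sd_percm: float = 0.0,
    overwrite: bool = False,
) -> dict:
    """Write the four-sample study fixture and return its manifest.

    Writes one temperature-series CSV per sample, a sample-metadata table, the
    Tg <-> moisture calibration table, a ground-truth JSON with every
    generation parameter, a pipeline config, and a manifest.  Defaults are
    noiseless so the fixture is an exact oracle; pass ``noise_sd_percm`` to
    emulate measurement scatter.  Reruns with the same arguments are
    byte-identical; an existing manifest without ``overwrite`` raises.
    """
    from . import io as tio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace it"
        )

    samples = []
    ground_truth: dict[str, dict] = {}
    for i, (sid, spec) in enumerate(STUDY_SAMPLES.items()):
        recipe = study_recipe(sid, noise_sd_percm=noise_sd_percm, seed=seed + i)
        series = simulate_temperature_series(recipe)
        series_file = f"series_{sid}.csv"
        tio.write_series(out / series_file, series)
        # start one ramp step above the breakpoint so the window holds
        # post-evaporation (high-segment) points only
        mob_window = (spec["breakpoints_K"][1] + 10.0, _T_MAX_K)
        samples.append(
            dict(
                sample_id=sid,
                series_file=series_file,
                thickness_cm=spec["thickness_cm"],
                mass_before_mg=_NOMINAL_MASS_MG,
                mass_after_mg=round(
                    _NOMINAL_MASS_MG * (1.0 + spec["uptake_percent"] / 100.0), 4
                ),
                storage_rh_percent=spec["storage_rh_percent"],
                tg_K=spec["tg_K"],
            )
        )
        ground_truth[sid] = dict(
            segments=[list(s) for s in recipe.segments],
            breakpoints_K=list(spec["breakpoints_K"]),
            t12_K=spec["t12_K"],
            t23_K=spec["t23_K"],
            low_segment=list(spec["low_segment"]),
            k_evap_perK=spec["k_evap_perK"],
            k_mob_perK=spec["k_mob_perK"],
            evap_window_K=list(spec["evap_window_K"]),
            mob_window_K=list(mob_window),
            uptake_percent=spec["uptake_percent"],
            moisture_percent=spec["moisture_percent"],
            noise_sd_percm=noise_sd_percm,
        )

    tio.write_sample_table(out / "samples.csv", samples)
    tio.write_calibration_table(
        out / "calibration.csv",
        tg_K=[spec["tg_K"] for spec in STUDY_SAMPLES.values()],
        moisture_percent=[spec["moisture_percent"] for spec in STUDY_SAMPLES.values()],
    )

    config = dict(
        sample_table="samples.csv",
        calibration_table="calibration.csv",
        probe_frequency_thz=1.0,
        seed=seed,
        gated_correction=True,
        output_dir="results",
        samples={
            sid: dict(
                series_file=f"series_{sid}.csv",
                breakpoints_K=list(spec["breakpoints_K"]),
                evap_window_K=list(spec["evap_window_K"]),
                mob_window_K=[spec["breakpoints_K"][1] + 10.0, _T_MAX_K],
            )
            for sid, spec in STUDY_SAMPLES.items()
        },
    )
    _write_json(out / "study_config.json", config)
    _write_json(out / "ground_truth.json", ground_truth)

    manifest = dict(
        seed=seed,
        noise_sd_percm=noise_sd_percm,
        samples=samples,
        files=dict(
            sample_table="samples.csv",
            calibration_table="calibration.csv",
            config="study_config.json",
            ground_truth="ground_truth.json",
        ),
    )
    _write_json(manifest_path, manifest)
    logger.info("wrote study fixture with %d samples to %s", len(samples), out)
    return manifest


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
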