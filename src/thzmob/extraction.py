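"""Absorption-coefficient extraction from terahertz pulse pairs.

A transmission THz-TDS measurement records the electric field of a picosecond
pulse twice: once through the sample slab and once through the empty beam path
(the reference).  The frequency-dependent absorption coefficient of a slab of
thickness ``d`` follows from the amplitude ratio of the two Fourier-transformed
fields,

    alpha(nu) = -(2 / d) * ln |E_sam(nu) / E_ref(nu)|,

with alpha in cm^-1 when d is in cm.  This module turns time-domain traces
into :class:`AbsorptionSpectrum` objects, extracts the absorption at a fixed
probe frequency (1 THz by convention) across a temperature ramp, applies the
purely cosmetic polynomial smoothing used for spectrum visualization, and
implements the dynamic-range rule that restricts quantitative analysis to a
reliable frequency band (0.5-1.4 THz by default).

Units are fixed internally: time in ps, frequency in THz (cycles/ps),
absorption in cm^-1, thickness in cm, temperature in K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Reliable quantitative analysis window for a typical THz-TDS transmission
#: setup; outside it the instrument dynamic range degrades.
DEFAULT_BAND_THZ = (0.5, 1.4)

_TIME_UNIFORMITY_TOL_PS = 1e-9
_MIN_TRACE_SAMPLES = 64


@dataclass(frozen=True)
class TimeDomainTrace:
    """A sampled electric-field pulse at one temperature.

    Parameters
    ----------
    time_ps:
        Strictly increasing, uniformly spaced sample times in ps.
    amplitude:
        Field amplitude in arbitrary units (same length as ``time_ps``).
    temperature_K:
        Temperature at which the trace was recorded.
    role:
        Either ``"sample"`` or ``"reference"``.
    """

    time_ps: np.ndarray
    amplitude: np.ndarray
    temperature_K: float
    role: str

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ps, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "time_ps", t)
        object.__setattr__(self, "amplitude", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("time and amplitude must be 1-D arrays of equal length")
        if t.size < _MIN_TRACE_SAMPLES:
            raise ValueError(f"trace needs >= {_MIN_TRACE_SAMPLES} samples, got {t.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise ValueError("trace contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.ptp(dt) > _TIME_UNIFORMITY_TOL_PS:
            raise ValueError("sample times must be uniformly spaced")
        if self.role not in ("sample", "reference"):
            raise ValueError(f"role must be 'sample' or 'reference', got {self.role!r}")

    @property
    def dt_ps(self) -> float:
        return float(self.time_ps[1] - self.time_ps[0])


@dataclass
class AbsorptionSpectrum:
    """Absorption coefficient alpha(nu) on a frequency grid with a valid band."""

    frequency_thz: np.ndarray
    alpha_percm: np.ndarray
    valid_band_thz: tuple[float, float]
    temperature_K: float
    #: True once the in-band points have been replaced by a polynomial fit;
    #: out-of-band points are never touched by smoothing.
    smoothed_in_band: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_thz, dtype=float)
        a = np.asarray(self.alpha_percm, dtype=float)
        self.frequency_thz, self.alpha_percm = f, a
        if f.ndim != 1 or a.shape != f.shape:
            raise ValueError("frequency and alpha must be 1-D arrays of equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        lo, hi = self.valid_band_thz
        if not (f[0] <= lo < hi <= f[-1]):
            raise ValueError(
                f"valid band ({lo}, {hi}) THz must lie within the grid "
                f"[{f[0]:.4g}, {f[-1]:.4g}] THz"
            )
        if not np.all(np.isfinite(a[self.in_band])):
            raise ValueError("alpha must be finite inside the valid band")

    @property
    def in_band(self) -> np.ndarray:
        lo, hi = self.valid_band_thz
        return (self.frequency_thz >= lo) & (self.frequency_thz <= hi)


@dataclass
class TemperatureSeries:
    """Absorption at one fixed probe frequency across a temperature ramp."""

    temperature_K: np.ndarray
    alpha_percm: np.ndarray
    probe_frequency_thz: float
    sample_id: str = ""
    se_percm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_K, dtype=float)
        a = np.asarray(self.alpha_percm, dtype=float)
        order = np.argsort(t)
        self.temperature_K = t[order]
        self.alpha_percm = a[order]
        if self.se_percm is not None:
            se = np.asarray(self.se_percm, dtype=float)
            if se.shape != t.shape:
                raise ValueError("se must match the temperature grid")
            self.se_percm = se[order]
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("temperature and alpha must be 1-D arrays of equal length")
        if np.unique(t).size != t.size:
            raise ValueError("temperatures must be unique")
        if not np.all(np.isfinite(a)):
            raise ValueError("alpha must be finite")

    def __len__(self) -> int:
        return self.temperature_K.size


def select_valid_band(
    frequency_thz: np.ndarray,
    ref_amplitude: np.ndarray,
    default_band_thz: tuple[float, float] = DEFAULT_BAND_THZ,
    snr_threshold: float = 5.0,
    noise_floor: Optional[float] = None,
) -> tuple[float, float]:
    """Narrow the default analysis band where the reference lacks dynamic range.

    A grid frequency is usable when the reference spectral amplitude exceeds
    ``snr_threshold`` times the noise floor.  The returned band is the longest
    contiguous usable run inside ``default_band_thz``; the rule only ever
    narrows the default, never widens it.  When ``noise_floor`` is not given it
    is estimated as the median reference amplitude over the top 10% of the
    frequency grid, where a pulsed source carries no signal.
    """
    f = np.asarray(frequency_thz, dtype=float)
    amp = np.abs(np.asarray(ref_amplitude, dtype=float))
    if noise_floor is None:
        tail = f >= f[0] + 0.9 * (f[-1] - f[0])
        noise_floor = float(np.median(amp[tail])) if np.any(tail) else 0.0
    lo, hi = default_band_thz
    band = (f >= lo) & (f <= hi)
    if not np.any(band):
        raise ValueError(f"no grid frequencies inside the default band ({lo}, {hi}) THz")
    ok = band & (amp >= snr_threshold * max(noise_floor, np.finfo(float).tiny))
    if not np.any(ok):
        raise ValueError(
            f"no frequency in ({lo}, {hi}) THz passes the dynamic-range "
            f"threshold {snr_threshold} x noise floor"
        )
    # longest contiguous passing run inside the band
    idx = np.flatnonzero(ok)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    best = max(runs, key=len)
    band_idx = np.flatnonzero(band)
    new_lo = lo if best[0] == band_idx[0] else float(f[best[0]])
    new_hi = hi if best[-1] == band_idx[-1] else float(f[best[-1]])
    if (new_lo, new_hi) != (lo, hi):
        logger.warning(
            "dynamic-range rule narrowed the band from (%.3g, %.3g) to (%.3g, %.3g) THz",
            lo, hi, new_lo, new_hi,
        )
    return (new_lo, new_hi)


def compute_absorption_spectrum(
    sample: TimeDomainTrace,
    reference: TimeDomainTrace,
    thickness_cm: float,
    window: Optional[str] = None,
    pad_factor: int = 2,
    default_band_thz: tuple[float, float] = DEFAULT_BAND_THZ,
    snr_threshold: float = 5.0,
    ref_floor: float = 1e-12,
) -> AbsorptionSpectrum:
    """Compute alpha(nu) = -(2/d) ln |E_sam / E_ref| from a pulse pair.

    Parameters
    ----------
    window:
        Optional taper name understood by :func:`scipy.signal.get_window`
        (e.g. ``"hann"``), applied to both traces before the transform.
        Default is no taper so that synthetic round trips close exactly.
    pad_factor:
        Integer zero-padding factor (>= 1) refining the frequency grid by
        trigonometric interpolation.  Off-grid queries should still go through
        :func:`extract_alpha_at`.
    ref_floor:
        Fraction of the peak reference amplitude below which a grid point is
        considered to carry no reference signal; alpha is masked (NaN) there
        with a logged warning.
    """
    if thickness_cm <= 0:
        raise ValueError(f"thickness must be positive, got {thickness_cm} cm")
    if sample.time_ps.shape != reference.time_ps.shape or not np.allclose(
        sample.time_ps, reference.time_ps, atol=_TIME_UNIFORMITY_TOL_PS, rtol=0.0
    ):
        raise ValueError("sample and reference traces must share the same time grid")
    if sample.temperature_K != reference.temperature_K:
        raise ValueError("sample and reference traces must share the same temperature")
    if not isinstance(pad_factor, (int, np.integer)) or pad_factor < 1:
        raise ValueError("pad_factor must be an integer >= 1")

    n = sample.time_ps.size
    taper = np.ones(n)
    if window is not None:
        from scipy.signal import get_window

        taper = get_window(window, n, fftbins=True)

    n_fft = int(pad_factor) * n
    freq = np.fft.rfftfreq(n_fft, d=sample.dt_ps)  # cycles/ps == THz
    e_sam = np.fft.rfft(sample.amplitude * taper, n=n_fft)
    e_ref = np.fft.rfft(reference.amplitude * taper, n=n_fft)

    mag_ref = np.abs(e_ref)
    floor = ref_floor * mag_ref.max()
    dead = mag_ref <= floor
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = -(2.0 / thickness_cm) * np.log(np.abs(e_sam) / mag_ref)
    band = select_valid_band(
        freq, mag_ref, default_band_thz=default_band_thz, snr_threshold=snr_threshold
    )
    in_band_dead = dead & (freq >= band[0]) & (freq <= band[1])
    if np.any(in_band_dead):
        logger.warning(
            "%d in-band frequencies have reference amplitude below the floor; masked",
            int(in_band_dead.sum()),
        )
    alpha[dead] = np.nan
    return AbsorptionSpectrum(
        frequency_thz=freq,
        alpha_percm=alpha,
        valid_band_thz=band,
        temperature_K=sample.temperature_K,
    )


def extract_alpha_at(spectrum: AbsorptionSpectrum, nu_thz: float) -> float:
    """Linearly interpolate alpha at ``nu_thz``; exact grid hits return the bin value."""
    lo, hi = spectrum.valid_band_thz
    if not (lo <= nu_thz <= hi):
        raise ValueError(
            f"probe frequency {nu_thz} THz outside the valid band ({lo}, {hi}) THz"
        )
    mask = spectrum.in_band & np.isfinite(spectrum.alpha_percm)
    if not np.any(mask):
        raise ValueError("no finite in-band points to interpolate")
    return float(
        np.interp(nu_thz, spectrum.frequency_thz[mask], spectrum.alpha_percm[mask])
    )


def build_temperature_series(
    spectra: Sequence[AbsorptionSpectrum],
    nu_thz: float = 1.0,
    replicates: Optional[Sequence[object]] = None,
    sample_id: str = "",
) -> TemperatureSeries:
    """Collapse a ramp of spectra into an alpha(nu, T) series.

    Spectra sharing a temperature are treated as replicates: alpha is the
    replicate mean and, when there are at least two, ``se`` is the standard
    error of the mean.  ``replicates`` optionally labels each spectrum with the
    sweep it belongs to; two spectra at the same temperature within one sweep
    are a duplicate and raise an error.
    """
    if len(spectra) == 0:
        raise ValueError("no spectra supplied")
    if replicates is not None and len(replicates) != len(spectra):
        raise ValueError("replicates labels must align with spectra")
    if replicates is not None:
        seen: set[tuple[object, float]] = set()
        for spec, rep in zip(spectra, replicates):
            key = (rep, float(spec.temperature_K))
            if key in seen:
                raise ValueError(
                    f"duplicate temperature {spec.temperature_K} K in replicate {rep!r}"
                )
            seen.add(key)
    values: dict[float, list[float]] = {}
    for spec in spectra:
        values.setdefault(float(spec.temperature_K), []).append(
            extract_alpha_at(spec, nu_thz)
        )
    temps = np.array(sorted(values))
    alpha = np.array([np.mean(values[t]) for t in temps])
    counts = np.array([len(values[t]) for t in temps])
    se = None
    if np.any(counts >= 2):
        se = np.array(
            [
                np.std(values[t], ddof=1) / np.sqrt(len(values[t]))
                if len(values[t]) >= 2
                else np.nan
                for t in temps
            ]
        )
    return TemperatureSeries(
        temperature_K=temps,
        alpha_percm=alpha,
        probe_frequency_thz=nu_thz,
        sample_id=sample_id,
        se_percm=se,
    )


def smooth_spectrum(spectrum: AbsorptionSpectrum, degree: int = 4) -> AbsorptionSpectrum:
    """Replace in-band alpha by a least-squares polynomial of the given degree.

    This is a purely empirical guide-the-eye smoother, not a physical model of
    the vibrational density of states.  Out-of-band points are left untouched;
    the result is flagged via ``smoothed_in_band``.
    """
    mask = spectrum.in_band & np.isfinite(spectrum.alpha_percm)
    n_in = int(mask.sum())
    if n_in < degree + 2:
        raise ValueError(
            f"smoothing needs >= {degree + 2} in-band points, got {n_in}"
        )
    poly = np.polynomial.Polynomial.fit(
        spectrum.frequency_thz[mask], spectrum.alpha_percm[mask], deg=degree
    )
    alpha = spectrum.alpha_percm.copy()
    alpha[mask] = poly(spectrum.frequency_thz[mask])
    return replace(spectrum, alpha_percm=alpha, smoothed_in_band=True)
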