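"""Absorption extraction: Eq.-1 inversion, band selection, series building, smoothing."""

import numpy as np
import pytest

from thzmob.extraction import (
    AbsorptionSpectrum,
    TimeDomainTrace,
    build_temperature_series,
    compute_absorption_spectrum,
    extract_alpha_at,
    select_valid_band,
    smooth_spectrum,
)
from thzmob.synthetic import PulseShape, SlabOptics, simulate_pulse_pair


def _bump_optics(d=0.06, peak=60.0, base=30.0):
    grid = np.linspace(0.2, 3.0, 300)
    alpha = base + (peak - base) * np.exp(-(((grid - 1.5) / 0.6) ** 2))
    return SlabOptics(grid, alpha, np.full_like(grid, 1.5), d)


def _spectrum(freq, alpha, band=(0.5, 1.4), temperature=80.0):
    return AbsorptionSpectrum(freq, alpha, band, temperature)


class TestComputeAbsorptionSpectrum:
    def test_identical_traces_give_zero_absorption(self):
        ref, _ = simulate_pulse_pair(_bump_optics())
        sam = TimeDomainTrace(ref.time_ps, ref.amplitude, ref.temperature_K, "sample")
        spec = compute_absorption_spectrum(sam, ref, 0.05)
        assert np.all(np.abs(spec.alpha_percm[spec.in_band]) < 1e-10)

    def test_known_amplitude_ratio_inverts_to_alpha(self):
        # uniform alpha = 40 cm^-1, d = 0.05 cm: ratio e^-1 -> alpha 40
        grid = np.linspace(0.2, 3.0, 100)
        optics = SlabOptics(grid, np.full_like(grid, 40.0), np.ones_like(grid), 0.05)
        ref, sam = simulate_pulse_pair(optics)
        spec = compute_absorption_spectrum(sam, ref, 0.05, pad_factor=1)
        np.testing.assert_allclose(spec.alpha_percm[spec.in_band], 40.0, rtol=1e-9)

    def test_generator_roundtrip_recovers_bump_within_one_percent(self):
        optics = _bump_optics()
        ref, sam = simulate_pulse_pair(optics)
        spec = compute_absorption_spectrum(sam, ref, optics.thickness_cm)
        m = spec.in_band
        injected = np.interp(spec.frequency_thz[m], optics.frequency_thz, optics.alpha_percm)
        np.testing.assert_allclose(spec.alpha_percm[m], injected, rtol=0.01)

    def test_alpha_is_intensive_under_slab_stacking(self):
        # doubling thickness squares the amplitude ratio but leaves alpha unchanged
        one = _bump_optics(d=0.05)
        two = SlabOptics(one.frequency_thz, one.alpha_percm, one.n_index, 0.10)
        ref1, sam1 = simulate_pulse_pair(one)
        ref2, sam2 = simulate_pulse_pair(two)
        spec1 = compute_absorption_spectrum(sam1, ref1, 0.05, pad_factor=1)
        spec2 = compute_absorption_spectrum(sam2, ref2, 0.10, pad_factor=1)
        np.testing.assert_allclose(
            spec1.alpha_percm[spec1.in_band], spec2.alpha_percm[spec2.in_band], rtol=1e-9
        )

    def test_common_amplitude_rescaling_cancels(self):
        ref, sam = simulate_pulse_pair(_bump_optics())
        spec = compute_absorption_spectrum(sam, ref, 0.06)
        ref2 = TimeDomainTrace(ref.time_ps, 3.7 * ref.amplitude, 80.0, "reference")
        sam2 = TimeDomainTrace(sam.time_ps, 3.7 * sam.amplitude, 80.0, "sample")
        spec2 = compute_absorption_spectrum(sam2, ref2, 0.06)
        np.testing.assert_allclose(
            spec.alpha_percm[spec.in_band], spec2.alpha_percm[spec2.in_band], rtol=1e-12
        )

    def test_mismatched_grids_and_bad_thickness_rejected(self):
        ref, sam = simulate_pulse_pair(_bump_optics())
        shifted = TimeDomainTrace(sam.time_ps + 1.0, sam.amplitude, 80.0, "sample")
        with pytest.raises(ValueError, match="time grid"):
            compute_absorption_spectrum(shifted, ref, 0.05)
        with pytest.raises(ValueError, match="thickness"):
            compute_absorption_spectrum(sam, ref, -0.05)


class TestTraceValidation:
    def test_too_short_nonuniform_and_nonfinite_traces_rejected(self):
        t = np.arange(128) * 0.05
        good = np.ones(128)
        with pytest.raises(ValueError, match="samples"):
            TimeDomainTrace(t[:32], good[:32], 80.0, "sample")
        jitter = t.copy()
        jitter[64] += 0.01
        with pytest.raises(ValueError, match="increasing|uniform"):
            TimeDomainTrace(jitter, good, 80.0, "sample")
        bad = good.copy()
        bad[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            TimeDomainTrace(t, bad, 80.0, "sample")


class TestExtractAlphaAt:
    def test_exact_grid_hit_returns_bin_value(self):
        freq = np.linspace(0.4, 1.6, 13)  # contains exactly 1.0
        alpha = np.linspace(30.0, 42.0, 13)
        spec = _spectrum(freq, alpha)
        assert extract_alpha_at(spec, 1.0) == alpha[np.argmin(np.abs(freq - 1.0))]

    def test_midpoint_query_on_linear_spectrum_is_exact(self):
        freq = np.array([0.4, 0.8, 1.2, 1.6])
        alpha = 10.0 + 25.0 * freq
        spec = _spectrum(freq, alpha)
        assert extract_alpha_at(spec, 1.0) == pytest.approx(10.0 + 25.0, abs=1e-12)

    def test_out_of_band_query_names_the_band(self):
        spec = _spectrum(np.linspace(0.2, 3.0, 50), np.full(50, 40.0))
        with pytest.raises(ValueError, match=r"0\.5.*1\.4"):
            extract_alpha_at(spec, 2.0)


class TestBuildTemperatureSeries:
    def _spec_at(self, temp, alpha):
        freq = np.linspace(0.4, 1.6, 25)
        return _spectrum(freq, np.full(25, alpha), temperature=temp)

    def test_single_spectrum_per_temperature_has_no_se(self):
        spectra = [self._spec_at(t, 30.0 + 0.02 * t) for t in (80.0, 90.0, 100.0)]
        series = build_temperature_series(spectra, 1.0)
        assert series.se_percm is None
        np.testing.assert_allclose(series.alpha_percm, 30.0 + 0.02 * series.temperature_K)

    def test_identical_replicates_have_zero_se(self):
        spectra = [self._spec_at(80.0, 35.0) for _ in range(3)]
        series = build_temperature_series(spectra, 1.0)
        assert series.se_percm is not None
        assert series.se_percm[0] == 0.0

    def test_se_estimates_sigma_over_sqrt_n(self):
        # mean reported se over many draws approximates sigma/sqrt(3) (n = 3)
        sigma, temps = 0.5, np.arange(80.0, 160.0, 10.0)
        rng = np.random.default_rng(42)
        ses = []
        for _ in range(200):
            spectra = [
                self._spec_at(t, 35.0 + rng.normal(0.0, sigma))
                for t in temps
                for _ in range(3)
            ]
            series = build_temperature_series(spectra, 1.0)
            ses.append(series.se_percm.mean())
        assert np.mean(ses) == pytest.approx(sigma / np.sqrt(3), rel=0.2)

    def test_duplicate_temperature_within_replicate_sweep_rejected(self):
        spectra = [self._spec_at(80.0, 35.0), self._spec_at(80.0, 36.0)]
        with pytest.raises(ValueError, match="duplicate"):
            build_temperature_series(spectra, 1.0, replicates=["run1", "run1"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no spectra"):
            build_temperature_series([], 1.0)


class TestSmoothSpectrum:
    def test_degree_four_polynomial_is_a_fixed_point(self):
        freq = np.linspace(0.2, 3.0, 200)
        coeffs = [40.0, -3.0, 8.0, -4.0, 0.6]
        alpha = sum(c * freq**k for k, c in enumerate(coeffs))
        spec = _spectrum(freq, alpha)
        smoothed = smooth_spectrum(spec, degree=4)
        assert smoothed.smoothed_in_band
        np.testing.assert_allclose(
            smoothed.alpha_percm[spec.in_band], alpha[spec.in_band], rtol=1e-10
        )

    def test_degree_zero_on_constant_data_returns_the_constant(self):
        freq = np.linspace(0.2, 3.0, 60)
        spec = _spectrum(freq, np.full(60, 37.0))
        smoothed = smooth_spectrum(spec, degree=0)
        np.testing.assert_allclose(smoothed.alpha_percm[spec.in_band], 37.0)

    def test_out_of_band_points_untouched(self):
        freq = np.linspace(0.2, 3.0, 200)
        alpha = 40.0 + 5.0 * np.sin(4 * freq)
        spec = _spectrum(freq, alpha)
        smoothed = smooth_spectrum(spec)
        out = ~spec.in_band
        np.testing.assert_array_equal(smoothed.alpha_percm[out], alpha[out])

    def test_smoothing_reduces_rms_error_against_truth(self):
        # truth is itself a quartic, so projection removes noise without bias
        freq = np.linspace(0.2, 3.0, 200)
        truth = 45.0 + 10.0 * freq - 6.0 * (freq - 1.2) ** 2 + 0.5 * (freq - 1.2) ** 4
        band = (freq >= 0.5) & (freq <= 1.4)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = truth + rng.normal(0.0, 1.0, freq.shape)
            spec = _spectrum(freq, noisy)
            smoothed = smooth_spectrum(spec, degree=4)
            rms_before = np.sqrt(np.mean((noisy[band] - truth[band]) ** 2))
            rms_after = np.sqrt(np.mean((smoothed.alpha_percm[band] - truth[band]) ** 2))
            assert rms_after < rms_before

    def test_too_few_in_band_points_rejected(self):
        freq = np.linspace(0.5, 1.4, 5)
        spec = _spectrum(freq, np.full(5, 40.0))
        with pytest.raises(ValueError, match="points"):
            smooth_spectrum(spec, degree=4)


class TestSelectValidBand:
    def test_clean_reference_keeps_default_band(self):
        freq = np.linspace(0.05, 5.0, 500)
        amp = np.exp(-((freq - 1.0) ** 2))  # strong everywhere in band
        assert select_valid_band(freq, amp, noise_floor=1e-9) == (0.5, 1.4)

    def test_noise_floor_crossing_narrows_the_upper_edge(self):
        freq = np.linspace(0.05, 5.0, 1000)
        amp = np.where(freq <= 1.2, 1.0, 1e-6)
        lo, hi = select_valid_band(freq, amp, noise_floor=1e-3, snr_threshold=5.0)
        assert lo == 0.5
        assert hi == pytest.approx(1.2, abs=freq[1] - freq[0])

    def test_vanishing_threshold_never_widens_beyond_default(self):
        freq = np.linspace(0.05, 5.0, 500)
        amp = np.ones_like(freq)
        assert select_valid_band(freq, amp, snr_threshold=0.0, noise_floor=1.0) == (0.5, 1.4)

    def test_fully_dead_band_is_an_error(self):
        freq = np.linspace(0.05, 5.0, 500)
        amp = np.full_like(freq, 1e-9)
        with pytest.raises(ValueError, match="threshold"):
            select_valid_band(freq, amp, noise_floor=1.0, snr_threshold=5.0)
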