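"""Segment fitting, breakpoint search and intersection temperatures."""

import numpy as np
import pytest

from thzmob.extraction import TemperatureSeries
from thzmob.fitting import (
    SegmentModel,
    fit_piecewise,
    fit_segment,
    intersect_segments,
    select_breakpoints,
)
from thzmob.synthetic import (
    STUDY_SAMPLES,
    SeriesRecipe,
    simulate_temperature_series,
    study_recipe,
)

LOW_REGION_ROWS = [spec["low_segment"] for spec in STUDY_SAMPLES.values()]


def _series(t, alpha, se=None):
    return TemperatureSeries(t, alpha, probe_frequency_thz=1.0, se_percm=se)


def _segment(a, b, c, t_range=(80.0, 420.0)):
    return SegmentModel(a, b, c, t_range, rss=0.0, n_points=10)


def _brute_intersection(seg_i, seg_j, bracket, step=0.001):
    """Independent oracle: finest-|difference| point on a dense grid."""
    t = np.arange(bracket[0], bracket[1] + step / 2, step)
    gap = np.abs(seg_i.alpha(t) - seg_j.alpha(t))
    return float(t[np.argmin(gap)])


class TestFitSegment:
    @pytest.mark.parametrize("a, b, c", LOW_REGION_ROWS)
    def test_noiseless_low_region_rows_recover_exactly(self, a, b, c):
        t = np.arange(80.0, 251.0, 10.0)
        series = _series(t, a * t + b + c / t)
        seg = fit_segment(series, (80.0, 250.0))
        np.testing.assert_allclose(
            [seg.A_percm_perK, seg.B_percm, seg.C_Kpercm], [a, b, c],
            rtol=1e-8, atol=1e-8,
        )
        assert seg.rss < 1e-16 * seg.n_points * max(1.0, b**2)

    def test_constant_series_fits_as_pure_offset(self):
        t = np.arange(80.0, 251.0, 10.0)
        seg = fit_segment(_series(t, np.full_like(t, 30.0)), (80.0, 250.0))
        np.testing.assert_allclose(
            [seg.A_percm_perK, seg.B_percm, seg.C_Kpercm], [0.0, 30.0, 0.0], atol=1e-10
        )

    def test_residuals_orthogonal_to_basis(self):
        rng = np.random.default_rng(11)
        t = np.arange(80.0, 251.0, 10.0)
        series = _series(t, 0.05 * t + 30.0 + 200.0 / t + rng.normal(0.0, 0.5, t.size))
        seg = fit_segment(series, (80.0, 250.0))
        resid = series.alpha_percm - seg.alpha(t)
        for basis in (t, np.ones_like(t), 1.0 / t):
            assert abs(np.dot(resid, basis)) < 1e-8 * np.linalg.norm(basis) * np.linalg.norm(
                series.alpha_percm
            )

    def test_fix_c_zero_drops_the_reciprocal_term(self):
        t = np.arange(80.0, 251.0, 10.0)
        seg = fit_segment(_series(t, 0.03 * t + 25.0), (80.0, 250.0), fix_c_zero=True)
        assert seg.C_Kpercm == 0.0
        np.testing.assert_allclose([seg.A_percm_perK, seg.B_percm], [0.03, 25.0], rtol=1e-10)

    def test_weighted_fit_follows_low_variance_points(self):
        t = np.arange(80.0, 161.0, 10.0)
        alpha = 0.02 * t + 30.0
        alpha_biased = alpha.copy()
        alpha_biased[-1] += 5.0  # outlier with huge se
        se = np.full_like(t, 0.01)
        se[-1] = 100.0
        seg = fit_segment(_series(t, alpha_biased, se=se), (80.0, 160.0))
        assert seg.alpha(100.0) == pytest.approx(0.02 * 100.0 + 30.0, abs=1e-3)

    def test_too_few_points_rejected(self):
        t = np.array([100.0, 110.0, 120.0])
        with pytest.raises(ValueError, match="need >= 4"):
            fit_segment(_series(t, 0.02 * t + 30.0), (100.0, 120.0))


class TestSelectBreakpoints:
    def test_two_segment_slope_change_found_within_one_grid_step(self):
        t = np.arange(80.0, 421.0, 10.0)
        alpha = np.where(t <= 300.0, 0.02 * t + 30.0, 0.09 * t + 30.0 - 0.07 * 300.0)
        bps = select_breakpoints(_series(t, alpha), n_segments=2)
        assert abs(bps[0] - 300.0) <= 10.0

    def test_degenerate_flat_objective_ties_to_smallest_breakpoint(self):
        t = np.arange(80.0, 421.0, 10.0)
        bps = select_breakpoints(
            _series(t, 0.03 * t + 28.0 + 150.0 / t), n_segments=2, min_points=4
        )
        # every split is exact; deterministic tie-break picks the smallest
        # admissible breakpoint (4th grid point)
        assert bps[0] == t[3]

    def test_three_segment_fixture_boundaries_recovered_under_noise(self):
        truth = STUDY_SAMPLES["pvpva2"]["breakpoints_K"]
        hits = 0
        n_trials = 100
        for seed in range(n_trials):
            recipe = study_recipe("pvpva2", noise_sd_percm=0.3, seed=seed)
            series = simulate_temperature_series(recipe)
            bps = select_breakpoints(series, n_segments=3, min_points=4)
            hits += all(abs(b - bt) <= 10.0 for b, bt in zip(bps, truth))
        assert hits >= 0.90 * n_trials

    def test_infeasible_min_points_rejected(self):
        t = np.arange(80.0, 161.0, 10.0)
        with pytest.raises(ValueError, match="points"):
            select_breakpoints(_series(t, 0.02 * t + 30.0), n_segments=3, min_points=4)


class TestIntersectSegments:
    def test_line_meets_constant_at_hundred(self):
        res = intersect_segments(_segment(1.0, 0.0, 0.0), _segment(0.0, 100.0, 0.0), (50.0, 150.0))
        assert res.temperature_K == pytest.approx(100.0, abs=1e-9)

    def test_reciprocal_meets_line_at_sqrt(self):
        res = intersect_segments(_segment(0.0, 0.0, 10000.0), _segment(1.0, 0.0, 0.0), (50.0, 150.0))
        assert res.temperature_K == pytest.approx(100.0, abs=1e-9)

    def test_coincident_segments_report_absent_intersection(self):
        res = intersect_segments(_segment(0.02, 30.0, 100.0), _segment(0.02, 30.0, 100.0), (100.0, 200.0))
        assert res.temperature_K is None
        assert res.status == "coincident"

    def test_two_in_bracket_roots_demand_a_narrower_bracket(self):
        # alpha_i - alpha_j = (T - 100)(T - 200)/T: roots at 100 and 200
        seg_i = _segment(1.0, -300.0, 20000.0)
        seg_j = _segment(0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="narrow"):
            intersect_segments(seg_i, seg_j, (50.0, 250.0))

    def test_no_root_in_bracket_is_absent_with_diagnostic(self):
        res = intersect_segments(_segment(1.0, 0.0, 0.0), _segment(0.0, 100.0, 0.0), (150.0, 300.0))
        assert res.temperature_K is None
        assert res.status == "no-root"
        assert res.roots_K  # the out-of-bracket root is reported

    def test_matches_dense_grid_scan_on_random_solvable_pairs(self):
        rng = np.random.default_rng(2024)
        bracket = (150.0, 400.0)
        cases = 0
        while cases < 200:
            seg_i = _segment(rng.uniform(-0.1, 0.1), rng.uniform(0, 60), rng.uniform(-300, 300))
            seg_j = _segment(rng.uniform(-0.1, 0.1), rng.uniform(0, 60), rng.uniform(-300, 300))
            t = np.linspace(*bracket, 2001)
            diff = seg_i.alpha(t) - seg_j.alpha(t)
            if np.count_nonzero(np.diff(np.sign(diff)) != 0) != 1:
                continue
            res = intersect_segments(seg_i, seg_j, bracket)
            assert res.temperature_K is not None
            brute = _brute_intersection(seg_i, seg_j, bracket)
            assert abs(res.temperature_K - brute) < 0.005
            cases += 1


class TestFitPiecewise:
    def test_three_region_synthetic_intersections_within_one_kelvin(self):
        recipe = study_recipe("pvpva2")
        series = simulate_temperature_series(recipe)
        pw = fit_piecewise(series, STUDY_SAMPLES["pvpva2"]["breakpoints_K"])
        assert pw.t12_K == pytest.approx(STUDY_SAMPLES["pvpva2"]["t12_K"], abs=1.0)
        assert pw.t23_K == pytest.approx(STUDY_SAMPLES["pvpva2"]["t23_K"], abs=1.0)

    def test_row_order_invariance(self):
        recipe = study_recipe("pvpva3")
        series = simulate_temperature_series(recipe)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(series))
        shuffled = TemperatureSeries(
            series.temperature_K[perm], series.alpha_percm[perm], 1.0
        )
        a = fit_piecewise(series, STUDY_SAMPLES["pvpva3"]["breakpoints_K"])
        b = fit_piecewise(shuffled, STUDY_SAMPLES["pvpva3"]["breakpoints_K"])
        assert a.t12_K == pytest.approx(b.t12_K, abs=1e-9)
        assert a.t23_K == pytest.approx(b.t23_K, abs=1e-9)

    def test_identical_generating_segments_give_absent_intersection(self):
        t = np.arange(80.0, 421.0, 10.0)
        series = _series(t, 0.03 * t + 28.0 + 150.0 / t)
        pw = fit_piecewise(series, [250.0])
        assert pw.t12_K is None
        assert pw.diagnostics["t12"].status in ("coincident", "no-root")

    def test_unsorted_breakpoints_rejected(self):
        t = np.arange(80.0, 421.0, 10.0)
        series = _series(t, 0.03 * t + 28.0)
        with pytest.raises(ValueError, match="increasing"):
            fit_piecewise(series, [300.0, 250.0])
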