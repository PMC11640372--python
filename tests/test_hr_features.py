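import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dialysentinel.hr_features import (
    Excursion,
    ExcursionSign,
    FittedCurve,
    HRSeries,
    WindowSpec,
    excursion_segments,
    extract_features,
    fit_curve,
    make_windows,
    max_area,
    resample_to_1hz,
    window_features,
)
from dialysentinel.synthetic import generate_case, idh_profile


def series(hr, t=None, **kw):
    hr = np.asarray(hr, dtype=float)
    if t is None:
        t = np.arange(hr.size, dtype=float)
    return HRSeries(time_s=t, hr_bpm=hr, **kw)


def brute_force_max_area(dev, sign):
    """Quadratic oracle: max |sum| over contiguous ranges of constant strict sign."""
    n = dev.size
    best = 0.0
    for i in range(n):
        total = 0.0
        for j in range(i, n):
            if sign * dev[j] <= 0:
                break
            total += abs(dev[j])
            best = max(best, total)
    return best


class TestHRSeriesValidation:
    def test_rejects_non_monotone_time(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            series([60, 61, 62], t=np.array([0.0, 2.0, 1.0]))

    def test_rejects_out_of_range_hr(self):
        with pytest.raises(ValueError, match="physiologic range"):
            series([60, 400, 62])

    def test_rejects_too_short(self):
        with pytest.raises(ValueError, match="at least 2"):
            series([60.0])


class TestResample:
    def test_integer_grid_unchanged(self):
        s = series(60 + np.sin(np.arange(100) / 7.0) * 5)
        out = resample_to_1hz(s)
        assert np.array_equal(out.hr_bpm, s.hr_bpm)
        assert np.array_equal(out.time_s, s.time_s)

    def test_midpoint_interpolation(self):
        s = series([60.0, 62.0], t=np.array([0.0, 2.0]))
        out = resample_to_1hz(s)
        assert np.array_equal(out.time_s, [0.0, 1.0, 2.0])
        assert np.allclose(out.hr_bpm, [60.0, 61.0, 62.0])

    def test_jittered_grid_recovers_line(self):
        # piecewise-linear signal sampled on a jittered grid: the resampled
        # values must sit on the analytic line
        rng = np.random.default_rng(7)
        t = np.cumsum(rng.uniform(0.5, 1.5, 200))
        a, b = 0.02, 70.0
        s = series(a * t + b, t=t)
        out = resample_to_1hz(s)
        assert np.max(np.abs(out.hr_bpm - (a * out.time_s + b))) < 1e-9

    def test_large_gap_refused(self):
        s = series([60.0, 61.0, 62.0], t=np.array([0.0, 40.0, 41.0]))
        with pytest.raises(ValueError, match="gap of 40.0 s"):
            resample_to_1hz(s)


class TestMakeWindows:
    def test_default_spec_eight_nested_ranges(self):
        s = series(np.full(2400, 80.0))
        ranges = make_windows(s, WindowSpec())
        assert len(ranges) == 8
        assert ranges[0] == (0, 300)
        assert ranges[-1] == (0, 2400)
        assert all(r[0] == 0 for r in ranges)

    def test_single_window(self):
        s = series(np.full(300, 80.0))
        assert make_windows(s, WindowSpec(lengths_s=(300,))) == [(0, 300)]

    def test_too_short_reports_counts(self):
        s = series(np.full(2399, 80.0))
        with pytest.raises(ValueError, match="2400 samples required.*2399"):
            make_windows(s, WindowSpec())

    def test_spec_rejects_non_multiples(self):
        with pytest.raises(ValueError, match="multiple of 300"):
            WindowSpec(lengths_s=(200,))


class TestFitCurve:
    def test_low_degree_polynomial_reproduced_exactly(self):
        x = np.linspace(-1, 1, 400)
        y = 80 + 5 * x - 3 * x**2 + 2 * x**3
        fit = fit_curve(y, degree=20)
        assert np.max(np.abs(fit.values - y)) < 1e-6

    def test_constant_signal(self):
        fit = fit_curve(np.full(300, 72.0), degree=20)
        assert np.allclose(fit.values, 72.0)

    def test_matches_normal_equations_oracle(self):
        # independent direct solution of the same LS problem via the
        # normal equations in a monomial basis on [-1, 1]
        rng = np.random.default_rng(3)
        y = 80 + 10 * np.sin(np.linspace(0, 6 * np.pi, 300)) + rng.normal(0, 2, 300)
        x = np.linspace(-1, 1, 300)
        V = np.vander(x, 21, increasing=True)
        coef = np.linalg.solve(V.T @ V, V.T @ y)
        oracle = V @ coef
        rss_oracle = np.sum((y - oracle) ** 2)
        fit = fit_curve(y, degree=20)
        rss = np.sum((y - fit.values) ** 2)
        assert rss == pytest.approx(rss_oracle, rel=1e-6)

    def test_window_shorter_than_degree_rejected(self):
        with pytest.raises(ValueError, match="must exceed polynomial degree"):
            fit_curve(np.full(20, 70.0), degree=20)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(11)
        y = 80 + rng.normal(0, 5, 600)
        fit = fit_curve(y, degree=20)
        assert abs(np.sum(y - fit.values)) < 1e-6 * y.size


class TestExcursions:
    def test_hand_enumerated_runs(self):
        dev = np.array([1.0, 2.0, -1.0, 3.0, -2.0])
        segs = excursion_segments(dev, 0.0)
        upper = [(s.start_index, s.end_index, s.area) for s in segs if s.sign == ExcursionSign.UPPER]
        lower = [(s.start_index, s.end_index, s.area) for s in segs if s.sign == ExcursionSign.LOWER]
        assert upper == [(0, 2, 3.0), (3, 4, 3.0)]
        assert lower == [(2, 3, 1.0), (4, 5, 2.0)]

    def test_all_zero_deviations_yield_no_excursions(self):
        assert excursion_segments(np.zeros(50), 0.0) == []

    def test_zero_splits_runs(self):
        segs = excursion_segments(np.array([1.0, 0.0, 1.0]), 0.0)
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 1), (2, 3)]

    def test_single_sustained_excursion(self):
        segs = excursion_segments(np.ones(300), 0.0)
        assert len(segs) == 1
        assert segs[0].area == pytest.approx(300.0)

    def test_sustained_20bpm_deviation_reaches_saturation_area(self):
        segs = excursion_segments(np.full(300, 20.0), 0.0)
        assert max_area(segs, ExcursionSign.UPPER) == pytest.approx(6000.0)

    def test_max_area_of_empty_list_is_zero(self):
        assert max_area([], ExcursionSign.UPPER) == 0.0

    def test_max_area_tie_keeps_earliest(self):
        segs = [
            Excursion(5, 7, ExcursionSign.UPPER, 4.0),
            Excursion(9, 11, ExcursionSign.UPPER, 4.0),
        ]
        assert max_area(segs, ExcursionSign.UPPER) == 4.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_quadratic_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        for _ in range(20):  # 200 random traces in total across trials
            n = int(rng.integers(5, 600))
            dev = rng.normal(0, 1, n)
            dev[rng.random(n) < 0.1] = 0.0  # force exact zeros into runs
            segs = excursion_segments(dev, 0.0)
            for sign, s in ((1, ExcursionSign.UPPER), (-1, ExcursionSign.LOWER)):
                assert max_area(segs, s) == pytest.approx(
                    brute_force_max_area(dev, sign), abs=1e-12
                )


class TestExtractFeatures:
    def test_constant_series_gives_zero_features(self):
        s = series(np.full(2400, 80.0))
        fv, per_window = extract_features(s)
        assert len(fv) == 16
        assert np.allclose(fv.values, 0.0)
        assert all(w.mean_hr == pytest.approx(80.0) for w in per_window)

    def test_feature_vector_has_16_entries_in_window_order(self):
        rng = np.random.default_rng(5)
        s = series(80 + rng.normal(0, 3, 2500))
        fv, per_window = extract_features(s)
        assert len(fv) == 16
        assert [w.length_s for w in per_window] == [300 * k for k in range(1, 9)]
        assert fv.values[14] == pytest.approx(per_window[-1].upper_area)
        assert fv.values[15] == pytest.approx(per_window[-1].lower_area)

    def test_requires_uniform_sampling(self):
        t = np.linspace(0, 3000, 2500)
        s = series(np.full(2500, 80.0), t=t)
        with pytest.raises(ValueError, match="resample"):
            extract_features(s)

    def test_synthetic_idh_case_hits_recorded_target(self):
        case = generate_case(idh_profile(), seed=12345)
        fv, _ = extract_features(case.series)
        assert fv.values[14] == pytest.approx(case.realized_targets["upper_2400"], rel=0.10)


@st.composite
def window_signals(draw):
    n = draw(st.integers(min_value=120, max_value=400))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    rng = np.random.default_rng(seed)
    return 80 + 8 * np.sin(np.linspace(0, rng.uniform(2, 20), n)) + rng.normal(0, 2, n)


class TestFitAndAreaProperties:
    @given(window_signals(), st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, y, c):
        # the LS fit is linear in the data, so scaling deviations scales areas
        base = window_features(y, len(y))
        scaled = window_features(np.mean(y) + c * (y - np.mean(y)), len(y))
        assert scaled.upper_area == pytest.approx(c * base.upper_area, rel=1e-9, abs=1e-9)
        assert scaled.lower_area == pytest.approx(c * base.lower_area, rel=1e-9, abs=1e-9)

    @given(window_signals(), st.floats(min_value=-30.0, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance(self, y, shift):
        base = window_features(y, len(y))
        moved = window_features(y + shift, len(y))
        assert moved.upper_area == pytest.approx(base.upper_area, abs=1e-6)
        assert moved.lower_area == pytest.approx(base.lower_area, abs=1e-6)

    @given(window_signals())
    @settings(max_examples=25, deadline=None)
    def test_fitted_mean_equals_raw_mean(self, y):
        fit = fit_curve(y, degree=20)
        assert np.mean(fit.values) == pytest.approx(np.mean(y), abs=1e-6)
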