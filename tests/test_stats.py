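"""Descriptive statistics against independent oracles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import esmview as ev
from esmview import stats
from esmview.schema import MISSING
from conftest import make_record


# --- independent brute-force oracles -------------------------------------

def quartile_oracle(sorted_vals, p):
    """Linear interpolation between order statistics (independent of numpy)."""
    n = len(sorted_vals)
    h = (n - 1) * p
    lo = int(h)
    if lo == n - 1:
        return float(sorted_vals[-1])
    return sorted_vals[lo] + (h - lo) * (sorted_vals[lo + 1] - sorted_vals[lo])


def boxplot_oracle(values):
    s = sorted(values)
    q1 = quartile_oracle(s, 0.25)
    med = quartile_oracle(s, 0.50)
    q3 = quartile_oracle(s, 0.75)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = [v for v in s if lo <= v <= hi]
    outliers = sorted(v for v in s if v < lo or v > hi)
    return med, q1, q3, inside[0], inside[-1], outliers


def wls_line(x, y, w):
    """Weighted least-squares line via the normal equations (independent path)."""
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return beta  # intercept, slope


def pointwise_loess_oracle(x, y, bandwidth, grid):
    """Direct definition: k nearest, tricube weights, WLS fit per grid point."""
    n = len(x)
    k = max(int(np.ceil(bandwidth * n)), 2)
    out = []
    for g in grid:
        d = np.abs(x - g)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out.append(y[idx].mean())
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        b0, b1 = wls_line(x[idx], y[idx], w)
        out.append(b0 + b1 * g)
    return np.array(out)


# --- boxplots --------------------------------------------------------------

class TestBoxplotSummary:
    def test_constant_data(self):
        s = stats.boxplot_summary([5, 5, 5, 5])
        assert (s.median, s.q1, s.q3) == (5, 5, 5)
        assert (s.whisker_low, s.whisker_high) == (5, 5)
        assert s.outliers == ()

    def test_far_point_is_outlier(self):
        s = stats.boxplot_summary([1, 2, 3, 4, 100])
        assert s.outliers == (100,)
        assert s.whisker_high == 4

    def test_whiskers_are_data_points(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(50, 20, 40).round(1)
        s = stats.boxplot_summary(vals)
        assert s.whisker_low in vals and s.whisker_high in vals

    def test_matches_bruteforce_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(1, 30)
            vals = rng.integers(0, 101, n).astype(float)
            s = stats.boxplot_summary(vals)
            med, q1, q3, wlo, whi, out = boxplot_oracle(vals)
            assert s.median == pytest.approx(med)
            assert s.q1 == pytest.approx(q1) and s.q3 == pytest.approx(q3)
            assert s.whisker_low == wlo and s.whisker_high == whi
            assert list(s.outliers) == out
            assert s.q1 <= s.median <= s.q3
            # whiskers are real data points at/beyond the hinges except in
            # tiny samples where every point past a hinge is an outlier
            if not out:
                assert s.whisker_low <= s.q1 and s.q3 <= s.whisker_high

    def test_missing_dropped_and_all_missing_errors(self):
        s = stats.boxplot_summary([MISSING, 1.0, float("nan"), 3.0])
        assert s.n == 2
        with pytest.raises(stats.InsufficientDataError):
            stats.boxplot_summary([MISSING])


class TestOrderItemsByMedian:
    def _summaries(self, medians):
        return [stats.boxplot_summary([m], code) for code, m in medians.items()]

    def test_single_group_ascending(self):
        order = stats.order_items_by_median(self._summaries({"a": 10, "b": 30, "c": 20}))
        assert order == ["a", "c", "b"]

    def test_ties_break_alphabetically(self):
        order = stats.order_items_by_median(self._summaries({"b": 10, "a": 10}))
        assert order == ["a", "b"]

    def test_groups_kept_separate_and_descending_option(self):
        summaries = self._summaries({"n1": 40, "p1": 10, "n2": 20, "p2": 30})
        pol = {"n1": "negative", "n2": "negative", "p1": "positive", "p2": "positive"}
        assert stats.order_items_by_median(summaries, pol) == ["n2", "n1", "p1", "p2"]
        assert stats.order_items_by_median(summaries, pol, ascending=False) == \
            ["n1", "n2", "p2", "p1"]

    def test_matches_recomputed_medians_on_simulated_data(self, four_week_dataset):
        frame = four_week_dataset.values_frame(
            four_week_dataset.questionnaire.slider_codes("negative"))
        summaries = [stats.boxplot_summary(frame[c].dropna().values, c)
                     for c in frame.columns]
        order = stats.order_items_by_median(summaries)
        medians = [float(np.median(frame[c].dropna())) for c in order]
        assert medians == sorted(medians)


# --- LOESS -----------------------------------------------------------------

class TestLoess:
    def test_default_bandwidth_is_02(self):
        t = np.arange(10.0)
        curve = stats.loess_smooth(t, t * 2)
        assert curve.bandwidth == 0.2 == stats.DEFAULT_BANDWIDTH

    @pytest.mark.parametrize("bandwidth", [0.2, 0.5, 1.0])
    def test_reproduces_linear_data_exactly(self, bandwidth):
        t = np.linspace(0, 30, 40)
        y = 3.0 + 1.7 * t
        curve = stats.loess_smooth(t, y, bandwidth=bandwidth)
        assert np.allclose(curve.fitted, y, rtol=0, atol=1e-9)

    def test_bandwidth_one_equals_global_tricube_wls(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 20, 25))
        y = 40 + 5 * np.sin(t) + rng.normal(0, 2, 25)
        grid = np.linspace(1, 19, 7)
        curve = stats.loess_smooth(t, y, bandwidth=1.0, grid_times=grid)
        for g, fit in zip(grid, curve.fitted):
            d = np.abs(t - g)
            w = (1 - (d / d.max()) ** 3) ** 3
            b0, b1 = wls_line(t, y, w)
            assert fit == pytest.approx(b0 + b1 * g, rel=1e-9, abs=1e-9)

    def test_matches_pointwise_oracle_on_fixture(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 60, 80))
        y = 30 + 20 * np.cos(t / 8) + rng.normal(0, 4, 80)
        grid = np.linspace(2, 58, 23)
        curve = stats.loess_smooth(t, y, bandwidth=0.3, grid_times=grid)
        oracle = pointwise_loess_oracle(t, y, 0.3, grid)
        assert np.allclose(curve.fitted, oracle, rtol=1e-9, atol=1e-9)

    def test_cross_check_against_statsmodels_lowess(self):
        """Independent implementation check at the data points (it=0)."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 50, 60))
        y = 50 + 15 * np.sin(t / 6) + rng.normal(0, 3, 60)
        ours = stats.loess_smooth(t, y, bandwidth=0.4).fitted
        theirs = lowess(y, t, frac=0.4, it=0, return_sorted=False)
        # different neighbourhood conventions at the edges; interior agrees
        assert np.allclose(ours[5:-5], theirs[5:-5], atol=1.0)

    def test_shift_scale_equivariance(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 10, 30))
        y = rng.uniform(0, 100, 30)
        base = stats.loess_smooth(t, y, bandwidth=0.4).fitted
        scaled = stats.loess_smooth(t, 3.0 * y + 7.0, bandwidth=0.4).fitted
        assert np.allclose(scaled, 3.0 * base + 7.0, atol=1e-8)

    def test_datetime_axis_measured_in_days(self):
        """09:00 vs 21:00 prompts are 0.5 day apart on the smoothing axis."""
        times = pd.to_datetime([
            "2017-03-06 09:00", "2017-03-06 21:00", "2017-03-07 09:00",
            "2017-03-07 21:00", "2017-03-08 09:00"]).values
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])  # linear in 0.5-day steps
        curve = stats.loess_smooth(times, y, bandwidth=1.0)
        assert np.allclose(curve.fitted, y, atol=1e-9)

    def test_too_few_points_and_missing_dropped(self):
        with pytest.raises(stats.InsufficientDataError):
            stats.loess_smooth([1, 2], [1, 2])
        curve = stats.loess_smooth(
            [0, 1, 2, 3], [0.0, np.nan, 2.0, 3.0], bandwidth=1.0)
        assert np.allclose(curve.fitted, [0, 1, 2, 3], atol=1e-9)

    def test_zero_time_spread_falls_back_to_mean(self):
        curve = stats.loess_smooth([2.0, 2.0, 2.0], [1.0, 2.0, 6.0], bandwidth=1.0)
        assert np.allclose(curve.fitted, 3.0)


# --- composites, episodes, missingness ------------------------------------

class TestComposite:
    def test_mean_of_available_items(self, questionnaire):
        rec = make_record(questionnaire, dt.datetime(2017, 3, 6, 9),
                          {c: MISSING for c in questionnaire.slider_codes("negative")})
        rec.values.update({"Sad": 10, "Appo": 20})
        ds = ev.ESMDataset(questionnaire=questionnaire, schedule=ev.PromptSchedule(),
                           records=[rec], study_start=dt.date(2017, 3, 6),
                           study_end=dt.date(2017, 3, 6))
        assert ev.composite_series(ds, "negative").iloc[0] == 15

    def test_unanswered_prompt_propagates_missing(self, questionnaire):
        rec = ev.PromptRecord.unanswered(dt.datetime(2017, 3, 6, 9), "morning",
                                         questionnaire)
        ds = ev.ESMDataset(questionnaire=questionnaire, schedule=ev.PromptSchedule(),
                           records=[rec], study_start=dt.date(2017, 3, 6),
                           study_end=dt.date(2017, 3, 6))
        assert np.isnan(ev.composite_series(ds, "negative").iloc[0])

    def test_noise_free_composite_equals_group_mean(self):
        cfg = ev.default_config(seed=0, study_start=dt.date(2017, 3, 6),
                                study_end=dt.date(2017, 3, 12), episodes=[],
                                block_missing_windows=[], default_sd=0.0, phi=0.0,
                                compliance_prob=1.0)
        ds = ev.simulate_dataset(cfg)
        codes = cfg.questionnaire.slider_codes("negative")
        expected = np.mean([round(cfg.mean_of(c)) for c in codes])
        series = ev.composite_series(ds, "negative")
        assert np.allclose(series.values, expected)

    def test_bad_polarity_rejected(self, four_week_dataset):
        with pytest.raises(ValueError):
            ev.composite_series(four_week_dataset, "neutral")


class TestFlagEpisodes:
    def test_flat_series_gives_no_windows(self):
        cfg = ev.default_config(seed=0, study_start=dt.date(2017, 3, 6),
                                study_end=dt.date(2017, 4, 30), episodes=[],
                                block_missing_windows=[], default_sd=0.0, phi=0.0,
                                compliance_prob=1.0)
        assert ev.flag_episodes(ev.simulate_dataset(cfg)) == []

    def test_single_strong_episode_found(self):
        episode = ev.EpisodeSpec(start_date=dt.date(2017, 4, 17),
                                 end_date=dt.date(2017, 5, 16),
                                 negative_shift=30, positive_shift=0, ramp_days=3)
        cfg = ev.default_config(seed=4, study_start=dt.date(2017, 3, 6),
                                study_end=dt.date(2017, 6, 25),
                                episodes=[episode], block_missing_windows=[],
                                default_sd=10.0)
        windows = ev.flag_episodes(ev.simulate_dataset(cfg))
        assert len(windows) == 1
        assert windows[0].overlaps(episode.start_date, episode.end_date)

    def test_insufficient_data_gives_empty_list(self, questionnaire):
        ds = ev.ESMDataset(questionnaire=questionnaire, schedule=ev.PromptSchedule(),
                           records=[], study_start=dt.date(2017, 3, 6),
                           study_end=dt.date(2017, 3, 6))
        assert ev.flag_episodes(ds) == []

    def test_bad_parameters_rejected(self, four_week_dataset):
        with pytest.raises(ValueError):
            ev.flag_episodes(four_week_dataset, k_sd=0)
        with pytest.raises(ValueError):
            ev.flag_episodes(four_week_dataset, min_days=0)


class TestMissingness:
    def test_fully_answered_no_gaps(self, questionnaire):
        records = [make_record(questionnaire, dt.datetime(2017, 3, 6, h))
                   for h in (9, 15, 21)]
        ds = ev.ESMDataset(questionnaire=questionnaire, schedule=ev.PromptSchedule(),
                           records=records, study_start=dt.date(2017, 3, 6),
                           study_end=dt.date(2017, 3, 6))
        miss = ev.missingness_summary(ds)
        assert miss.gaps == []
        assert all(f == 0 for f in miss.item_missing_fraction.values())
        assert miss.answered_per_day.loc[dt.date(2017, 3, 6)] == 3

    def test_two_week_block_gives_42_prompt_gap(self):
        cfg = ev.default_config(
            seed=2, study_start=dt.date(2017, 3, 6), study_end=dt.date(2017, 6, 25),
            episodes=[], compliance_prob=1.0,
            block_missing_windows=[(dt.date(2017, 5, 10), dt.date(2017, 5, 23))])
        miss = ev.missingness_summary(ev.simulate_dataset(cfg))
        assert len(miss.gaps) == 1
        start, end, n = miss.gaps[0]
        assert n == 42  # 3 prompts/day x 14 days
        assert start == dt.datetime(2017, 5, 10, 9)
        assert end == dt.datetime(2017, 5, 23, 21)

    def test_counts_conserved(self, four_week_dataset):
        miss = ev.missingness_summary(four_week_dataset)
        frame = four_week_dataset.values_frame()
        for code in frame.columns:
            observed = int(frame[code].notna().sum())
            assert miss.item_missing_count[code] + observed == miss.n_prompts
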