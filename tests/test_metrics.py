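"""Meal-metric unit tests against closed forms and brute-force oracles."""

import numpy as np
import pytest

from mealphot.metrics import (
    WINDOWS,
    CorrelationResult,
    baseline_variability,
    delta_z,
    heatmap_aggregate,
    lick_rate,
    metric_correlation,
    mid_meal_mean,
    phase_means,
    stratum_label,
    window_response,
)
from mealphot.trials import SessionAnalysis, TrialMatrix, TrialRecord
from mealphot.session import SessionMeta


def make_matrix(values, rate=50.0, pre=10.0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    return TrialMatrix(values=values, time_axis=-pre + np.arange(n) / rate,
                       trial_indices=np.arange(values.shape[0]), units="zscore")


class TestWindowResponse:
    def test_zero_matrix(self):
        m = make_matrix(np.zeros((3, 3000)))
        assert np.array_equal(window_response(m, WINDOWS["peri_licking"]),
                              np.zeros(3))

    def test_indicator_row_column_count_arithmetic(self):
        c = 2.5
        row = np.zeros(3000)
        t = -10.0 + np.arange(3000) / 50.0
        row[(t >= 1.0) & (t < 10.0)] = c
        m = make_matrix(row)
        assert window_response(m, WINDOWS["peri_licking"])[0] == pytest.approx(c)
        assert window_response(m, WINDOWS["consumption"])[0] == pytest.approx(c * 9 / 10)

    def test_window_presets_span_the_documented_intervals(self):
        assert (WINDOWS["peri_licking"].start, WINDOWS["peri_licking"].end) == (1.0, 10.0)
        assert (WINDOWS["consumption"].start, WINDOWS["consumption"].end) == (0.0, 10.0)
        assert (WINDOWS["peri_licking_short"].end) == 9.0
        assert (WINDOWS["cue"].start, WINDOWS["cue"].end) == (0.0, 1.0)
        assert (WINDOWS["extended"].end) == 20.0

    def test_empty_window_errors(self):
        m = make_matrix(np.zeros((1, 100)), pre=10.0)  # axis spans [-10, -8)
        with pytest.raises(ValueError, match="no samples"):
            window_response(m, WINDOWS["peri_licking"])


class TestPhaseMeans:
    def test_constant_responses(self):
        early, late, overlap = phase_means(np.full(40, 3.3))
        assert early == late == pytest.approx(3.3)
        assert not overlap

    def test_arithmetic_sequence(self):
        early, late, _ = phase_means(np.arange(1.0, 31.0))
        assert early == pytest.approx(8.0)   # mean(1..15)
        assert late == pytest.approx(23.0)   # mean(16..30)

    def test_overlap_flagged_between_15_and_29(self):
        _, _, overlap = phase_means(np.arange(20.0))
        assert overlap
        e, l, overlap = phase_means(np.arange(30.0))
        assert not overlap

    def test_undefined_below_phase_size(self):
        early, late, _ = phase_means(np.arange(14.0))
        assert np.isnan(early) and np.isnan(late)


class TestDeltaZ:
    def test_constant_is_zero(self):
        assert delta_z(np.full(30, 1.7)) == pytest.approx(0.0)

    def test_arithmetic_sequence_1_to_90(self):
        assert delta_z(np.arange(1.0, 91.0)) == pytest.approx(85.0)

    def test_missing_below_tail(self):
        assert np.isnan(delta_z(np.arange(4.0)))


class TestLickRate:
    def make_trial(self, licks):
        return TrialRecord(index=0, cue_time=300.0, triggered=True,
                           lick_times_in_trial=np.asarray(licks, dtype=float))

    def test_no_licks(self):
        assert lick_rate(self.make_trial([]), WINDOWS["cue"]) == 0.0

    def test_four_licks_in_cue_second(self):
        t = self.make_trial([0.1, 0.4, 0.6, 0.9, 1.5])
        assert lick_rate(t, WINDOWS["cue"]) == pytest.approx(4.0)

    def test_reward_window_rate(self):
        t = self.make_trial(np.linspace(1.0, 10.0, 18, endpoint=False))
        assert lick_rate(t, WINDOWS["peri_licking"]) == pytest.approx(2.0)


class TestStrata:
    def test_quoted_bin_edges(self):
        assert stratum_label(44) == "30-44"
        assert stratum_label(45) == "45-59"

    def test_below_fifteen_unstratified(self):
        assert stratum_label(0) is None
        assert stratum_label(14) is None

    def test_exhaustive_enumeration_0_to_90(self):
        bins = [(15, 29), (30, 44), (45, 59), (60, 74), (75, 90)]
        for n in range(0, 91):
            expected = next((f"{lo}-{hi}" for lo, hi in bins if lo <= n <= hi), None)
            assert stratum_label(n) == expected


class TestMidMeal:
    def test_constant(self):
        assert mid_meal_mean(np.full(40, 2.2)) == pytest.approx(2.2)

    def test_ordinal_sequence(self):
        # responses equal their 1-based ordinal -> mean of 15..29 = 22
        assert mid_meal_mean(np.arange(1.0, 41.0)) == pytest.approx(22.0)

    def test_missing_below_29(self):
        assert np.isnan(mid_meal_mean(np.arange(1.0, 29.0)))


class TestBaselineVariability:
    def test_constant_segment(self):
        s, sds, short = baseline_variability(np.full(50 * 100, 2.0), 50.0)
        assert s == 0.0 and not short

    def test_white_noise_recovers_sigma(self, rng):
        sigma = 0.7
        x = rng.normal(0, sigma, size=50 * 300)
        s, _, _ = baseline_variability(x, 50.0)
        assert s == pytest.approx(sigma, rel=0.05)

    def test_ramp_closed_form(self):
        # rolling SD of a linear ramp: slope * dt * sqrt((n^2 - 1) / 12)
        slope, rate, win = 0.02, 50.0, 30.0
        n = round(win * rate)
        x = slope * np.arange(50 * 200) / rate
        s, sds, _ = baseline_variability(x, rate, window=win)
        expected = slope / rate * np.sqrt((n**2 - 1) / 12.0)
        assert np.allclose(sds, expected, rtol=1e-9)

    def test_short_segment_flagged(self):
        s, sds, short = baseline_variability(np.arange(10.0), 50.0, window=30.0)
        assert short and sds.size == 1


def make_analysis(mouse, rows, triggered, licks_per_trial=None, included=True):
    """SessionAnalysis stub with a prebuilt z-matrix."""
    rows = np.atleast_2d(rows)
    n = rows.shape[0]
    trials = []
    for k in range(n):
        licks = (licks_per_trial or {}).get(k, [2.0])
        trials.append(TrialRecord(index=k, cue_time=300.0 + 60.0 * k,
                                  triggered=bool(triggered[k]),
                                  lick_times_in_trial=np.asarray(licks, dtype=float)))
    m = make_matrix(rows)
    sa = SessionAnalysis(meta=SessionMeta(mouse, f"{mouse}_s0"), trials=trials,
                         dff=m, z=m, included=included, n_triggered=int(sum(triggered)))
    return sa


class TestHeatmapAggregate:
    def test_single_mouse_identical_trials(self):
        row = np.linspace(0, 1, 3000)
        sa = make_analysis("m0", np.tile(row, (4, 1)), [True] * 4)
        bundle = heatmap_aggregate([sa])
        assert np.allclose(bundle.grand_mean, row)

    def test_grand_mean_unweighted_across_mice(self):
        a = make_analysis("m0", np.full((8, 3000), 1.0), [True] * 8)
        b = make_analysis("m1", np.full((2, 3000), 3.0), [True] * 2)
        bundle = heatmap_aggregate([a, b])
        # (1 + 3) / 2 regardless of the 8-vs-2 trial counts
        assert np.allclose(bundle.grand_mean, 2.0)

    def test_untriggered_trials_never_contribute(self):
        rows = np.vstack([np.full(3000, 1.0), np.full(3000, 100.0)])
        sa = make_analysis("m0", rows, [True, False])
        bundle = heatmap_aggregate([sa])
        assert np.allclose(bundle.grand_mean, 1.0)

    def test_excluded_sessions_skipped(self):
        sa = make_analysis("m0", np.full((2, 3000), 1.0), [True] * 2, included=False)
        with pytest.raises(ValueError):
            heatmap_aggregate([sa])


class TestMetricCorrelation:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = metric_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_hand_worked_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        # textbook covariance / product of sds
        r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        res = metric_correlation(x, y)
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        assert res.n == 5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            metric_correlation(np.ones(5), np.arange(5.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            metric_correlation([1.0, 2.0], [1.0, 2.0])


class TestMouseAggregation:
    def make_metrics(self):
        import pandas as pd
        rows = []
        for mouse, vals in (("m0", [0.2, 0.4]), ("m1", [1.0, 3.0])):
            for i, v in enumerate(vals):
                rows.append({"mouse": mouse, "session": f"{mouse}_s{i}",
                             "diet": "NCD", "condition": "NCD", "sex": "M",
                             "body_weight": 25.0, "included": True,
                             "n_triggered": 40 + i, "early_mean": v,
                             "late_mean": v + 1.0, "delta_z": 1.0,
                             "mid_meal_mean": v, "cue_lick_rate": 3.0,
                             "reward_lick_rate": 2.0,
                             "baseline_rolling_sd": 0.1})
        return pd.DataFrame(rows)

    def test_unweighted_mean_per_mouse(self):
        from mealphot.metrics import aggregate_by_mouse

        agg = aggregate_by_mouse(self.make_metrics())
        assert len(agg) == 2
        m0 = agg[agg.mouse == "m0"].iloc[0]
        assert m0["early_mean"] == pytest.approx(0.3)
        assert m0["n_sessions"] == 2

    def test_mouse_level_phase_table(self):
        from mealphot.metrics import phase_table

        long = phase_table(self.make_metrics(), level="mouse")
        assert len(long) == 4  # 2 mice x 2 phases
        early_m1 = long[(long.Mouse == "m1") & (long.MealPhase == "early")]
        assert early_m1["value"].iloc[0] == pytest.approx(2.0)


class TestSpeedWindows:
    def test_constant_speed_recovered_in_both_windows(self):
        from mealphot.session import SessionRecording, SessionMeta
        from mealphot.signal import ChannelTrace
        from mealphot.trials import analyze_session
        from mealphot.metrics import session_metrics

        cues = 300.0 + 60.0 * np.arange(40)
        rec = SessionRecording(
            meta=SessionMeta("m0", "s0"),
            trace465=ChannelTrace(np.full(50 * 2800, 2.0)),
            cue_times=cues, lick_times=cues + 0.2,
            speed_samples=np.full(10 * 2800, 3.5), speed_rate=10.0)
        row = session_metrics(analyze_session(rec))
        assert row["pre_cue_speed"] == pytest.approx(3.5)
        assert row["post_reward_speed"] == pytest.approx(3.5)

    def test_missing_speed_yields_nan(self):
        sa = make_analysis("m0", np.zeros((2, 3000)), [True, True])
        from mealphot.metrics import session_metrics

        row = session_metrics(sa)
        assert np.isnan(row["pre_cue_speed"])
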