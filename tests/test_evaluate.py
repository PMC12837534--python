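import numpy as np
import pandas as pd
import pytest

from foalwatch.evaluate import (
    alerts_per_mare,
    build_validation_window,
    circadian_summary,
    confusion,
    confusion_sweep,
    label_days,
    std6h_distribution,
)
from foalwatch.predict import sweep
from foalwatch.simulate import SynthConfig, generate_cohort

from conftest import events_frame


def _days(mare, values, foal_date, n_days=None, evaluable=None):
    """Daily STd-6h rows ending on foal_date (one value per day, oldest first)."""
    n = len(values)
    dates = pd.date_range(end=foal_date, periods=n, freq="D")
    return pd.DataFrame(
        {
            "mare_id": mare,
            "eval_time": dates + pd.Timedelta(hours=15),
            "std6h": values,
            "n_diffs": 12,
            "evaluable": evaluable if evaluable is not None else [True] * n,
        }
    )


class TestLabelDays:
    def test_same_evening_foaling_labels_that_day(self):
        days = _days("m1", [-0.3], "2024-03-05")
        events = events_frame([("m1", "2024-03-05T23:40")])
        outcomes, excluded = label_days(days, events)
        assert excluded.empty
        assert bool(outcomes.iloc[0]["foaling_tonight"])

    def test_post_midnight_foaling_credited_to_preceding_eval_date(self):
        days = _days("m1", [-0.3, -0.1], "2024-03-06")
        events = events_frame([("m1", "2024-03-06T02:00")])
        outcomes, _ = label_days(days, events)
        by_date = outcomes.set_index("eval_date")["foaling_tonight"]
        assert bool(by_date[pd.Timestamp("2024-03-05")])
        assert not bool(by_date[pd.Timestamp("2024-03-06")])

    def test_daytime_foaling_mare_is_excluded(self):
        days = pd.concat(
            [_days("m1", [-0.3], "2024-03-05"), _days("m2", [-0.2], "2024-03-05")],
            ignore_index=True,
        )
        events = events_frame(
            [("m1", "2024-03-06T12:00"), ("m2", "2024-03-05T21:00")]
        )
        outcomes, excluded = label_days(days, events)
        assert set(outcomes["mare_id"]) == {"m2"}
        assert excluded.iloc[0]["mare_id"] == "m1"
        assert excluded.iloc[0]["reason"] == "daytime_foaling"

    def test_six_am_boundary_counts_as_daytime(self):
        days = _days("m1", [-0.3], "2024-03-05")
        events = events_frame([("m1", "2024-03-06T06:00")])
        outcomes, excluded = label_days(days, events)
        assert outcomes.empty
        assert not excluded.empty

    def test_mare_without_event_is_all_negative_days(self):
        days = _days("m1", [-0.3, -0.4], "2024-03-05")
        outcomes, excluded = label_days(days, events_frame([]))
        assert excluded.empty
        assert not outcomes["foaling_tonight"].any()


class TestValidationWindow:
    def test_long_history_capped_at_seven_days(self):
        days = _days("m1", [0.0] * 9 + [-0.3], "2024-03-10")
        events = events_frame([("m1", "2024-03-10T22:00")])
        outcomes, _ = label_days(days, events)
        window, excluded = build_validation_window(outcomes)
        assert excluded.empty
        assert len(window) == 7
        assert window["foaling_tonight"].sum() == 1
        assert window["eval_date"].max() == pd.Timestamp("2024-03-10")

    def test_four_evaluable_days_excludes_mare(self):
        days = _days("m1", [0.0, 0.0, 0.0, -0.3], "2024-03-10")
        events = events_frame([("m1", "2024-03-10T22:00")])
        outcomes, _ = label_days(days, events)
        window, excluded = build_validation_window(outcomes)
        assert window.empty
        assert excluded.iloc[0]["reason"] == "insufficient_days"

    def test_gap_truncates_consecutive_window(self):
        evaluable = [True, True, False, True, True, True, True, True, True, True]
        days = _days("m1", [0.0] * 9 + [-0.3], "2024-03-10", evaluable=evaluable)
        events = events_frame([("m1", "2024-03-10T22:00")])
        outcomes, _ = label_days(days, events)
        window, _ = build_validation_window(outcomes)
        # the non-evaluable day 2024-03-03 truncates: window is 03-04..03-10
        assert len(window) == 7
        assert window["eval_date"].min() == pd.Timestamp("2024-03-04")

    def test_mare_day_budget_of_the_study_design(self):
        """22 mares with 5-7 day windows average 6.7 days (147 total)."""
        frames, events = [], []
        for i, n in enumerate([7] * 15 + [6] * 7):
            mare = f"m{i:02d}"
            frames.append(_days(mare, [0.0] * (n - 1) + [-0.3], "2024-03-10"))
            events.append((mare, "2024-03-10T22:00"))
        outcomes, _ = label_days(pd.concat(frames, ignore_index=True), events_frame(events))
        window, excluded = build_validation_window(outcomes)
        assert excluded.empty
        assert len(window) == 147
        per_mare = window.groupby("mare_id").size()
        assert per_mare.between(5, 7).all()
        assert round(per_mare.mean(), 1) == 6.7


class TestConfusion:
    @pytest.mark.parametrize(
        "tp,fp,fn,sens,prec",
        [(18, 17, 4, 81.8, 51.4), (6, 1, 16, 27.3, 85.7), (20, 47, 2, 90.9, 29.9)],
    )
    def test_statistics_from_count_triples(self, tp, fp, fn, sens, prec):
        """Printed-table arithmetic: sens = 100*TP/(TP+FN), prec = 100*TP/(TP+FP), 1 dp."""
        frames, events = [], []
        values = [-0.25] * tp + [0.0] * fn          # foaling-day values
        nonfoal = [-0.25] * fp + [0.0] * (120 - fp)  # non-foaling days
        it = iter(nonfoal)
        for i, v in enumerate(values):
            mare = f"m{i:02d}"
            week = [next(it) for _ in range(5)] + [v]
            frames.append(_days(mare, week, "2024-03-10"))
            events.append((mare, "2024-03-10T22:00"))
        outcomes, _ = label_days(pd.concat(frames, ignore_index=True), events_frame(events))
        window, _ = build_validation_window(outcomes)
        decisions = sweep(window.rename(columns={"eval_date": "x"}).assign(
            eval_time=lambda d: d["x"] + pd.Timedelta(hours=15)), thresholds=(-0.2,))
        row = confusion(window, decisions, -0.2)
        assert (row["tp"], row["fp"], row["fn"]) == (tp, fp, fn)
        assert row["sensitivity"] == sens
        assert row["precision"] == prec

    def test_empty_denominators_reported_absent(self):
        outcomes = pd.DataFrame(
            columns=["mare_id", "eval_date", "std6h", "n_diffs", "evaluable", "foaling_tonight"]
        )
        decisions = pd.DataFrame(columns=["mare_id", "eval_date", "threshold", "alert"])
        decisions["threshold"] = decisions["threshold"].astype(float)
        row = confusion(outcomes, decisions, -0.2)
        assert (row["tp"], row["fp"], row["fn"]) == (0, 0, 0)
        assert np.isnan(row["sensitivity"]) and np.isnan(row["precision"])

    def test_uncovered_outcome_day_is_an_error(self):
        days = _days("m1", [0.0] * 6 + [-0.3], "2024-03-10")
        events = events_frame([("m1", "2024-03-10T22:00")])
        outcomes, _ = label_days(days, events)
        window, _ = build_validation_window(outcomes)
        decisions = sweep(days.iloc[:3], thresholds=(-0.2,))
        with pytest.raises(ValueError, match="cover"):
            confusion(window, decisions, -0.2)


class TestAlertsPerMare:
    def test_study_figure(self):
        assert alerts_per_mare({"tp": 18, "fp": 17}, 22) == 1.6

    def test_zero_alerts(self):
        assert alerts_per_mare({"tp": 0, "fp": 0}, 22) == 0.0

    def test_one_alert_per_mare(self):
        assert alerts_per_mare({"tp": 22, "fp": 0}, 22) == 1.0

    def test_invalid_mare_count(self):
        with pytest.raises(ValueError):
            alerts_per_mare({"tp": 1, "fp": 1}, 0)


class TestCircadianSummary:
    def test_odd_count_median(self):
        records = pd.DataFrame(
            {
                "mare_id": "m1",
                "timestamp": pd.to_datetime(
                    ["2024-03-05T10:00", "2024-03-05T10:30", "2024-03-05T11:00"]
                ),
                "temp_c": [36.6, 36.7, 36.8],
            }
        )
        events = events_frame([("m1", "2024-03-05T23:00")])
        cs = circadian_summary(records, events)
        row = cs.periods.iloc[0]
        assert row["day_offset"] == -1
        assert row["median"] == pytest.approx(36.7)

    def test_identical_values_collapse_percentiles(self):
        records = pd.DataFrame(
            {
                "mare_id": "m1",
                "timestamp": pd.date_range("2024-03-05T09:00", periods=10, freq="30min"),
                "temp_c": 36.8,
            }
        )
        events = events_frame([("m1", "2024-03-05T23:00")])
        row = circadian_summary(records, events).periods.iloc[0]
        assert row["p25"] == row["median"] == row["p75"] == 36.8

    def test_data_after_final_1500_never_enters(self):
        records = pd.DataFrame(
            {
                "mare_id": "m1",
                "timestamp": pd.to_datetime(["2024-03-05T14:00", "2024-03-05T16:00"]),
                "temp_c": [36.8, 20.0],  # the 16:00 reading is after the anchor
            }
        )
        events = events_frame([("m1", "2024-03-05T23:00")])
        cs = circadian_summary(records, events)
        assert cs.periods["n_values"].sum() == 1
        assert cs.periods.iloc[0]["median"] == 36.8


class TestStd6hDistribution:
    def test_fractions_per_day_offset(self):
        frames, events = [], []
        for i in range(22):
            # foaling-day value below the cut for 18 of 22 mares
            v = -0.3 if i < 18 else 0.0
            frames.append(_days(f"m{i:02d}", [0.0] * 6 + [v], "2024-03-10"))
            events.append((f"m{i:02d}", "2024-03-10T22:00"))
        outcomes, _ = label_days(pd.concat(frames, ignore_index=True), events_frame(events))
        dist = std6h_distribution(outcomes, cut=-0.2).set_index("day_offset")
        assert dist.loc[-1, "n_mares"] == 22
        assert dist.loc[-1, "fraction_below"] == 81.8
        assert dist.loc[-7, "fraction_below"] == 0.0

    def test_small_n_rounding(self):
        frames, events = [], []
        for i in range(17):
            v = -0.3 if i == 0 else 0.0
            frames.append(_days(f"m{i:02d}", [v], "2024-03-10"))
            events.append((f"m{i:02d}", "2024-03-10T22:00"))
        # single day per mare -> that day is the foaling day, offset -1
        outcomes, _ = label_days(pd.concat(frames, ignore_index=True), events_frame(events))
        dist = std6h_distribution(outcomes, cut=-0.2).set_index("day_offset")
        assert dist.loc[-1, "n_mares"] == 17
        assert dist.loc[-1, "fraction_below"] == 5.9
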