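import numpy as np
import pandas as pd
import pytest

from conftest import basic_metadata, make_day_records
from lifespace import cleaning


class TestFlagDays:
    def test_visitor_week_excludes_all_seven_days(self, no_reports):
        days = make_day_records("h1", "2019-03-01", 60)
        reports = pd.DataFrame(
            {
                "home_id": ["h1"],
                "week_start": [pd.Timestamp("2019-03-20")],
                "overnight_visitors": [True],
                "away_overnight": [False],
            }
        )
        flagged = cleaning.flag_days(days, reports, basic_metadata(["h1"]))
        marked = flagged[flagged["visitor_week"]]["date"]
        assert list(marked) == list(pd.date_range("2019-03-20", periods=7))
        assert not flagged.loc[flagged["visitor_week"], "eligible"].any()

    def test_covid_cutoff_depends_on_site(self, no_reports):
        days_r = make_day_records("hr", "2020-03-01", 30)
        days_o = make_day_records("ho", "2020-03-01", 30)
        meta = pd.concat([basic_metadata(["hr"], site="RUSH"), basic_metadata(["ho"], site="OHSU")])
        flagged = cleaning.flag_days(pd.concat([days_r, days_o]), no_reports, meta)
        day = pd.Timestamp("2020-03-21")
        rush = flagged[(flagged.home_id == "hr") & (flagged.date == day)]
        ohsu = flagged[(flagged.home_id == "ho") & (flagged.date == day)]
        assert rush["post_covid"].iloc[0]  # Illinois: after 2020-03-20
        assert not ohsu["post_covid"].iloc[0]  # Oregon cutoff is 2020-03-23

    def test_burn_in_and_weekend_rule(self, no_reports):
        # Monday 2019-01-07 start: first 14 calendar days are burn-in, so
        # the first eligible day is Monday 2019-01-21; weekends never count
        days = make_day_records("h1", "2019-01-07", 100)
        flagged = cleaning.flag_days(days, no_reports, basic_metadata(["h1"]))
        eligible = flagged[flagged["eligible"]]["date"]
        expected = [
            d
            for d in pd.date_range("2019-01-07", periods=100)
            if d >= pd.Timestamp("2019-01-21") and d.dayofweek < 5
        ]
        assert list(eligible) == expected

    def test_move_date_excludes_later_days(self, no_reports):
        days = make_day_records("h1", "2019-01-01", 40)
        meta = basic_metadata(["h1"])
        meta.loc["h1", "move_dates"] = "2019-01-20"
        flagged = cleaning.flag_days(days, no_reports, meta)
        assert flagged.loc[flagged.date > "2019-01-20", "post_move"].all()
        assert not flagged.loc[flagged.date <= "2019-01-20", "post_move"].any()

    def test_missing_site_metadata_fatal(self, no_reports):
        days = make_day_records("h1", "2019-01-01", 5)
        with pytest.raises(ValueError, match="h1"):
            cleaning.flag_days(days, no_reports, basic_metadata(["other"]))

    def test_exclusion_is_monotone(self, no_reports):
        """Adding an exclusion source never grows the eligible-day set."""
        days = make_day_records("h1", "2019-01-01", 80)
        meta = basic_metadata(["h1"])
        base = cleaning.flag_days(days, no_reports, meta)
        reports = pd.DataFrame(
            {
                "home_id": ["h1"],
                "week_start": [pd.Timestamp("2019-02-01")],
                "overnight_visitors": [False],
                "away_overnight": [True],
            }
        )
        more = cleaning.flag_days(days, reports, meta)
        base_set = set(base[base.eligible]["date"])
        more_set = set(more[more.eligible]["date"])
        assert more_set <= base_set


class TestSensorOutages:
    def test_silent_sensor_day_flagged(self, small_cohort):
        outages = cleaning.detect_sensor_outages(small_cohort.events)
        # every simulator-injected outage day must be detected
        for home_id, gt in small_cohort.truth.items():
            injected = gt.daily.loc[gt.daily["outage"], "date"]
            found = set(
                outages[(outages.home_id == home_id) & outages.sensor_inactive]["date"]
            )
            assert set(injected) <= found


class TestEligibilityWindow:
    def _flagged(self, n_days, home_id="h1", start="2019-01-07"):
        days = make_day_records(home_id, start, n_days)
        return cleaning.flag_days(
            days,
            pd.DataFrame(columns=["home_id", "week_start", "overnight_visitors", "away_overnight"]),
            basic_metadata([home_id]),
        )

    def test_four_week_window_caps_at_20_weekdays(self):
        sel = cleaning.eligibility_window(self._flagged(100), "four_week")
        assert len(sel) == 20
        assert (sel["date"].dt.dayofweek < 5).all()
        assert sel["date"].min() >= pd.Timestamp("2019-01-21")

    def test_home_with_19_eligible_days_dropped(self):
        # Mon 2019-01-07 start: burn-in ends 2019-01-20, and 39 total days
        # leave exactly 19 eligible weekdays - under the 4-week floor
        flagged = self._flagged(39)
        n_elig = int(flagged["eligible"].sum())
        assert n_elig == 19
        sel = cleaning.eligibility_window(flagged, "four_week")
        assert sel.empty

    def test_longitudinal_requires_more_than_180_days(self):
        short = self._flagged(260)  # ~175 eligible weekdays
        assert 20 <= short["eligible"].sum() <= 180
        assert cleaning.eligibility_window(short, "longitudinal").empty
        long = self._flagged(300)  # ~204 eligible weekdays
        sel = cleaning.eligibility_window(long, "longitudinal")
        assert sel["home_id"].nunique() == 1
        assert len(sel) > 180

    def test_interruptions_ignored_in_four_week_count(self, no_reports):
        # a mid-window visitor week just pushes the window later
        days = make_day_records("h1", "2019-01-07", 120)
        reports = pd.DataFrame(
            {
                "home_id": ["h1"],
                "week_start": [pd.Timestamp("2019-01-28")],
                "overnight_visitors": [True],
                "away_overnight": [False],
            }
        )
        flagged = cleaning.flag_days(days, reports, basic_metadata(["h1"]))
        sel = cleaning.eligibility_window(flagged, "four_week")
        assert len(sel) == 20
        assert not sel["date"].between("2019-01-28", "2019-02-03").any()


class TestRemoveOutliers:
    def test_all_equal_removes_nothing(self):
        vals = pd.Series([2.0] * 10)
        kept, removed = cleaning.remove_outliers(vals)
        assert len(removed) == 0 and len(kept) == 10

    def test_planted_six_sd_point_removed(self):
        # constructed so the planted point still exceeds 5 SD after being
        # included in the mean/SD computation itself
        rng = np.random.default_rng(0)
        base = pd.Series(rng.normal(10, 1, size=200))
        vals = pd.concat([base, pd.Series([10 + 40 * base.std()])], ignore_index=True)
        dev = (vals - vals.mean()).abs() / vals.std(ddof=1)
        assert dev.iloc[-1] > 5  # verify the construction
        kept, removed = cleaning.remove_outliers(vals)
        assert list(removed) == [200]

    def test_values_just_inside_threshold_retained(self):
        vals = pd.Series([0.0] * 47 + [1.0, -1.0])
        sd = vals.std(ddof=1)
        assert 4.85 < (vals.abs().max() - vals.mean()) / sd < 5.0
        kept, removed = cleaning.remove_outliers(vals)
        assert len(removed) == 0
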