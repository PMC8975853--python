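"""Inclusion filters and the normalized weekly-rhythm matrix."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from screenrhythms import (
    EventLog,
    WeeklyProfile,
    assemble_matrix,
    build_weekly_profile,
    filter_participants,
    population_average,
    profiles_from_log,
)


def make_log(user_events, window):
    """user_events: {user: [(event, timestamp), ...]}"""
    rows = [
        {"user": u, "event": e, "timestamp": pd.Timestamp(t)}
        for u, evs in user_events.items()
        for e, t in evs
    ]
    data = pd.DataFrame(rows).sort_values(["user", "timestamp"])
    return EventLog(data.reset_index(drop=True), window)


def daily_events(user, start, n_days, per_day, hour=10):
    """per_day screen-on + screen-off pairs at the given hour, daily."""
    out = []
    for d in range(n_days):
        day = dt.datetime.combine(start + dt.timedelta(days=d), dt.time(hour))
        for i in range(per_day):
            out.append(("screen_on", day + dt.timedelta(minutes=2 * i)))
            out.append(("screen_off", day + dt.timedelta(minutes=2 * i + 1)))
    return out


WINDOW10 = (dt.date(2014, 1, 6), dt.date(2014, 1, 6) + dt.timedelta(days=69))  # 10 weeks


class TestFilterParticipants:
    def test_active_user_retained(self):
        # active all 70 days, 30 on+off pairs/day = 420 events/week combined
        log = make_log({"a": daily_events("a", WINDOW10[0], 70, 30)}, WINDOW10)
        assert filter_participants(log).participants == ["a"]

    def test_low_day_coverage_excluded(self):
        # plenty of events but active on only 40/70 days (0.57 < 0.80)
        log = make_log({"a": daily_events("a", WINDOW10[0], 40, 60)}, WINDOW10)
        assert filter_participants(log).participants == []

    def test_low_event_rate_excluded(self):
        # active every day but 5 pairs/day = 70 events/week < 280
        log = make_log({"a": daily_events("a", WINDOW10[0], 70, 5)}, WINDOW10)
        assert filter_participants(log).participants == []

    def test_empty_log_raises(self):
        empty = EventLog(
            pd.DataFrame({"user": pd.Series(dtype=str),
                          "event": pd.Series(dtype=str),
                          "timestamp": pd.Series(dtype="datetime64[ns]")}),
            WINDOW10,
        )
        with pytest.raises(ValueError):
            filter_participants(empty)

    def test_filter_monotone_in_thresholds(self):
        log = make_log(
            {
                "a": daily_events("a", WINDOW10[0], 70, 30),
                "b": daily_events("b", WINDOW10[0], 60, 25),
                "c": daily_events("c", WINDOW10[0], 30, 5),
            },
            WINDOW10,
        )
        strict = set(filter_participants(log, 0.8, 280).participants)
        loose_days = set(filter_participants(log, 0.5, 280).participants)
        loose_both = set(filter_participants(log, 0.5, 50).participants)
        assert strict <= loose_days <= loose_both


class TestBuildWeeklyProfile:
    def test_single_event_single_mass(self):
        p = build_weekly_profile([dt.datetime(2014, 1, 6, 10, 15)], "a")  # Monday 10:15
        assert p.fractions[10] == 1.0
        assert p.fractions.sum() == 1.0

    def test_uniform_one_event_per_bin(self):
        base = dt.datetime(2014, 1, 6)
        p = build_weekly_profile([base + dt.timedelta(hours=h) for h in range(168)], "a")
        np.testing.assert_allclose(p.fractions, np.full(168, 1 / 168))

    def test_hand_counted_fractions(self):
        # 3 events Monday 09:xx, 1 event Friday 22:xx -> bins 9 and 4*24+22=118
        events = [
            dt.datetime(2014, 1, 6, 9, 1),
            dt.datetime(2014, 1, 6, 9, 20),
            dt.datetime(2014, 1, 6, 9, 59),
            dt.datetime(2014, 1, 10, 22, 30),
        ]
        p = build_weekly_profile(events, "a")
        assert p.fractions[9] == 0.75
        assert p.fractions[118] == 0.25
        assert p.fractions.sum() == 1.0

    def test_zero_events_raise(self):
        with pytest.raises(ValueError):
            build_weekly_profile([], "a")


class TestAssembleMatrix:
    def test_two_profiles(self):
        f = np.zeros(168); f[0] = 1.0
        g = np.zeros(168); g[1] = 1.0
        m = assemble_matrix([WeeklyProfile("a", f, 1), WeeklyProfile("b", g, 1)])
        assert m.X.shape == (2, 168)
        assert m.row_ids == ["a", "b"]

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            WeeklyProfile("a", np.ones(24) / 24, 24)

    def test_duplicate_ids_rejected(self):
        f = np.zeros(168); f[0] = 1.0
        with pytest.raises(ValueError, match="duplicate"):
            assemble_matrix([WeeklyProfile("a", f, 1), WeeklyProfile("a", f, 1)])

    def test_population_scale_matrix(self, default_profiles):
        assert default_profiles.X.shape == (200, 168)

    def test_rows_are_stochastic(self, default_profiles):
        X = default_profiles.X
        assert (X >= 0).all()
        np.testing.assert_allclose(X.sum(axis=1), 1.0, atol=1e-9)

    def test_csv_round_trip(self, tmp_path, default_profiles):
        out = tmp_path / "profiles.csv"
        default_profiles.to_csv(out)
        back = type(default_profiles).from_csv(out)
        assert back.row_ids == default_profiles.row_ids
        np.testing.assert_allclose(back.X, default_profiles.X, atol=1e-12)


class TestPopulationAverage:
    def test_identical_rows_mean_is_row(self):
        f = np.zeros(168); f[5] = 1.0
        m = assemble_matrix([WeeklyProfile("a", f, 1), WeeklyProfile("b", f, 1)])
        np.testing.assert_allclose(population_average(m), f)

    def test_two_one_hot_rows(self):
        f = np.zeros(168); f[0] = 1.0
        g = np.zeros(168); g[1] = 1.0
        avg = population_average(
            assemble_matrix([WeeklyProfile("a", f, 1), WeeklyProfile("b", g, 1)])
        )
        assert avg[0] == avg[1] == 0.5

    def test_night_hours_are_quietest(self, default_population, default_profiles):
        """The population mean rhythm dips during the planted sleep hours."""
        avg = population_average(default_profiles)
        assert abs(avg.sum() - 1.0) < 1e-9
        daily = avg.reshape(7, 24).mean(axis=0)
        night = daily[[3, 4, 5]].mean()   # deep night, inside most sleep windows
        day = daily[[10, 13, 16, 19]].mean()
        assert night < 0.2 * day


def test_profiles_from_log_matches_hand_binning():
    window = (dt.date(2014, 1, 6), dt.date(2014, 1, 12))
    events = {
        "a": [("screen_on", dt.datetime(2014, 1, 6, 8)),
              ("screen_on", dt.datetime(2014, 1, 7, 8)),
              ("screen_off", dt.datetime(2014, 1, 7, 9))],
    }
    m = profiles_from_log(make_log(events, window))
    assert m.X[0, 8] == 0.5          # Monday 08h
    assert m.X[0, 24 + 8] == 0.5     # Tuesday 08h; screen_off ignored
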