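"""Screen-event log I/O and hour-of-week calendar arithmetic.

The raw input is a comma-separated log of phone screen events: one row per
screen turning on or off, with a participant identifier, the event type and
a timestamp.  All timestamps are treated as local wall-clock time; on DST
transition days the 23- or 25-hour wall-clock day is binned by wall-clock
hour with no correction, since behaviour is anchored to local social time.

The week runs Monday to Sunday (ISO-8601), so hour-of-week 0 is Monday
00:00-01:00 and hour 167 is Sunday 23:00-24:00.  Sub-hour event times are
floored to the containing hour everywhere downstream.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_TYPES = ("screen_on", "screen_off")
CSV_COLUMNS = ("user", "event", "timestamp")
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

HOURS_PER_WEEK = 168


@dataclass(frozen=True)
class EventRecord:
    """A single screen on/off event."""

    participant_id: str
    event_type: str
    timestamp: dt.datetime

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"event_type must be one of {EVENT_TYPES}, got {self.event_type!r}"
            )


@dataclass
class EventLog:
    """An ordered collection of screen events within an observation window.

    Parameters
    ----------
    data
        DataFrame with columns ``user`` (str), ``event`` (str, one of
        :data:`EVENT_TYPES`) and ``timestamp`` (datetime64), sorted by
        ``(user, timestamp)``.
    window
        Closed ``(start_date, end_date)`` interval; every record's date
        falls inside it.
    """

    data: pd.DataFrame
    window: tuple[dt.date, dt.date] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if self.window is None:
            if len(self.data):
                ts = self.data["timestamp"]
                self.window = (ts.min().date(), ts.max().date())
            else:
                self.window = (dt.date(2014, 1, 6), dt.date(2014, 12, 21))
        if len(self.data):
            dates = self.data["timestamp"].dt.date
            if dates.min() < self.window[0] or dates.max() > self.window[1]:
                raise ValueError("records fall outside the observation window")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_days(self) -> int:
        """Number of calendar days in the (closed) observation window."""
        return (self.window[1] - self.window[0]).days + 1

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.data["user"]))

    def screen_on(self) -> pd.DataFrame:
        return self.data[self.data["event"] == "screen_on"]

    def for_participant(self, participant_id: str) -> pd.DataFrame:
        return self.data[self.data["user"] == participant_id]

    def restrict(self, participant_ids) -> "EventLog":
        keep = self.data["user"].isin(set(participant_ids))
        return EventLog(self.data[keep].copy(), self.window)

    def write(self, path) -> None:
        """Write the log in the canonical CSV dialect (see :func:`read_event_log`)."""
        out = self.data.copy()
        out["timestamp"] = out["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
        out.to_csv(path, index=False, columns=list(CSV_COLUMNS))


def week_window(year: int, first_week: int, last_week: int) -> tuple[dt.date, dt.date]:
    """Closed date interval spanning ISO weeks ``first_week``..``last_week``.

    The default analysis window, weeks 2-51 of 2014, runs Monday 2014-01-06
    to Sunday 2014-12-21 (350 days).
    """
    _validate_weeks(year, first_week, last_week)
    start = dt.date.fromisocalendar(year, first_week, 1)
    end = dt.date.fromisocalendar(year, last_week, 7)
    return start, end


def _validate_weeks(year: int, first_week: int, last_week: int) -> None:
    for week in (first_week, last_week):
        try:
            dt.date.fromisocalendar(year, week, 1)
        except ValueError as exc:
            raise ValueError(f"invalid ISO week {week} for year {year}") from exc
    if last_week < first_week:
        raise ValueError(
            f"inverted week range: first_week={first_week} > last_week={last_week}"
        )


def days_in_week_range(year: int, first_week: int, last_week: int) -> int:
    """Number of days covered by ISO weeks ``first_week``..``last_week``."""
    _validate_weeks(year, first_week, last_week)
    return 7 * (last_week - first_week + 1)


def hour_of_week(timestamp) -> int:
    """Map a datetime to its hour-of-week bin in [0, 167].

    Monday 00:xx is bin 0, Sunday 23:xx is bin 167: ``24 * weekday + hour``.
    """
    ts = pd.Timestamp(timestamp)
    return 24 * ts.weekday() + ts.hour


def read_event_log(path, window: tuple[dt.date, dt.date]) -> EventLog:
    """Read a screen-event CSV, validate it, and restrict it to ``window``.

    The dialect is fixed: header ``user,event,timestamp``; ``event`` is
    ``screen_on`` or ``screen_off``; ``timestamp`` is ISO-8601
    ``YYYY-MM-DDTHH:MM:SS``.  Rows dated outside ``window`` are dropped (the
    count is logged); malformed rows raise a :class:`ValueError` naming the
    first offending row (1-based, excluding the header).
    """
    try:
        raw = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise FileNotFoundError(f"event log not found: {path}")
    if list(raw.columns) != list(CSV_COLUMNS):
        raise ValueError(
            f"expected header {','.join(CSV_COLUMNS)}, got {','.join(raw.columns)}"
        )
    bad_event = ~raw["event"].isin(EVENT_TYPES)
    if bad_event.any():
        row = int(np.flatnonzero(bad_event.to_numpy())[0]) + 1
        raise ValueError(
            f"row {row}: unknown event token {raw['event'].iloc[row - 1]!r}"
        )
    ts = pd.to_datetime(raw["timestamp"], format=TIMESTAMP_FORMAT, errors="coerce")
    bad_ts = ts.isna() & raw["timestamp"].notna() | raw["timestamp"].isna()
    if bad_ts.any():
        row = int(np.flatnonzero(bad_ts.to_numpy())[0]) + 1
        raise ValueError(
            f"row {row}: unparseable timestamp {raw['timestamp'].iloc[row - 1]!r}"
        )
    data = pd.DataFrame(
        {"user": raw["user"].astype(str), "event": raw["event"], "timestamp": ts}
    )
    dates = data["timestamp"].dt.date
    inside = (dates >= window[0]) & (dates <= window[1])
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("dropped %d rows outside window %s..%s", n_dropped, *window)
    data = data[inside]
    data = data.sort_values(["user", "timestamp"], kind="mergesort")
    return EventLog(data.reset_index(drop=True), window)
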