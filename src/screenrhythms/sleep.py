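"""Sleep/wake inference from the longest nightly run of phone inactivity.

For each participant and each 24-hour day window, screen-on events are
reduced to a binary hourly presence vector.  The longest maximal run of
inactive hours is taken to be the night's sleep episode: its first hour is
the sleep time, the first active hour after it the wake-up time, its length
the sleep duration, and its midpoint the mid-sleep time (a standard
chronotype proxy).

Day windows are anchored at noon (12:00 to 12:00 the next day) so that a
typical night's sleep is contiguous within one window; midnight-anchored
windows would bisect most sleep episodes.  Per-person typical values are
the modes of the per-day distributions (robust to outlier nights), with
hours ordered on the noon-anchored axis (12, 13, ..., 23, 0, ..., 11) so
that the night hours around midnight stay contiguous.  Typical sleep
duration is the plain mean of the nightly durations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventLog

logger = logging.getLogger(__name__)

ANCHOR_HOUR = 12  # day windows run noon -> noon


@dataclass
class SleepRecord:
    participant_id: str
    day_index: int
    sleep_hour: int
    wake_hour: int
    mid_sleep_hour: float
    duration_hours: int


@dataclass
class SleepSummary:
    participant_id: str
    typical_sleep: int
    typical_wake: int
    typical_mid_sleep: int
    mean_duration: float


def hourly_presence(timestamps, window_start) -> np.ndarray:
    """Binary 24-vector: 1 iff >= 1 screen-on event in that hour of the window."""
    start = pd.Timestamp(window_start)
    presence = np.zeros(24, dtype=int)
    for ts in pd.to_datetime(pd.Series(list(timestamps))):
        offset = int((ts - start) // pd.Timedelta(hours=1))
        if 0 <= offset < 24:
            presence[offset] = 1
    return presence


def _longest_zero_runs(active: np.ndarray):
    """Vectorized longest zero-run per row of a (R, 24) 0/1 array.

    Returns (start, length) positions within the window; earliest run wins
    ties.  length 0 means all active, 24 means all inactive.
    """
    rows = active.shape[0]
    run = np.zeros(rows, dtype=int)
    best_len = np.zeros(rows, dtype=int)
    best_start = np.full(rows, -1, dtype=int)
    for h in range(active.shape[1]):
        inactive = active[:, h] == 0
        run = np.where(inactive, run + 1, 0)
        better = run > best_len  # strict: earliest maximal run is kept
        best_len = np.where(better, run, best_len)
        best_start = np.where(better, h - run + 1, best_start)
    return best_start, best_len


def detect_sleep(
    presence: np.ndarray, participant_id: str = "", day_index: int = 0,
    anchor_hour: int = ANCHOR_HOUR,
) -> SleepRecord | None:
    """Locate the sleep episode in one day window's presence vector.

    Returns ``None`` when no episode can be delimited: all hours active
    (no gap), all hours inactive (no activity), or the longest gap runs to
    the end of the window so no wake-up is observed.
    """
    active = np.asarray(presence, dtype=int).reshape(1, -1)
    if active.shape[1] != 24:
        raise ValueError("presence vector must have 24 entries")
    start, length = _longest_zero_runs(active)
    s, ln = int(start[0]), int(length[0])
    if ln == 0 or ln == 24 or s + ln >= 24:
        return None
    sleep_hour = (anchor_hour + s) % 24
    wake_hour = (anchor_hour + s + ln) % 24
    mid = (anchor_hour + s + ln / 2.0) % 24
    return SleepRecord(participant_id, day_index, sleep_hour, wake_hour, mid, ln)


def presence_grid(log: EventLog, participant_id: str) -> np.ndarray:
    """(n_days, 24) hourly screen-on presence for one participant."""
    on = log.screen_on()
    ts = on.loc[on["user"] == participant_id, "timestamp"]
    start = log.window[0]
    idx = (
        (ts.dt.date - start).map(lambda d: d.days).to_numpy() * 24
        + ts.dt.hour.to_numpy()
    )
    flat = np.zeros(log.n_days * 24, dtype=int)
    flat[idx] = 1
    return flat.reshape(log.n_days, 24)


def records_from_grid(grid: np.ndarray, participant_id: str,
                      anchor_hour: int = ANCHOR_HOUR) -> list[SleepRecord]:
    """Sleep records for every noon-anchored window of a presence grid."""
    flat = np.asarray(grid, dtype=int).ravel()
    n_days = len(flat) // 24
    n_windows = n_days - 1
    if n_windows < 1:
        return []
    offsets = np.arange(n_windows) * 24 + anchor_hour
    windows = flat[offsets[:, None] + np.arange(24)]
    start, length = _longest_zero_runs(windows)
    ok = (length > 0) & (length < 24) & (start + length < 24)
    records = []
    for d in np.flatnonzero(ok):
        s, ln = int(start[d]), int(length[d])
        records.append(
            SleepRecord(
                participant_id,
                int(d),
                (anchor_hour + s) % 24,
                (anchor_hour + s + ln) % 24,
                (anchor_hour + s + ln / 2.0) % 24,
                ln,
            )
        )
    n_missing = n_windows - len(records)
    if n_missing > n_windows / 2:
        logger.warning(
            "participant %s: sleep undetectable on %d/%d days",
            participant_id, n_missing, n_windows,
        )
    return records


def sleep_records(log: EventLog, anchor_hour: int = ANCHOR_HOUR) -> pd.DataFrame:
    """Per-day sleep records for every participant in the log.

    Columns: ``user, day, sleep_hour, wake_hour, mid_sleep_hour, duration``.
    Days with no delimitable episode are absent.
    """
    rows = []
    for user in log.participants:
        grid = presence_grid(log, user)
        for rec in records_from_grid(grid, user, anchor_hour):
            rows.append(
                (user, rec.day_index, rec.sleep_hour, rec.wake_hour,
                 rec.mid_sleep_hour, rec.duration_hours)
            )
    return pd.DataFrame(
        rows,
        columns=["user", "day", "sleep_hour", "wake_hour", "mid_sleep_hour", "duration"],
    )


def records_from_counts(counts: np.ndarray, ids,
                        anchor_hour: int = ANCHOR_HOUR) -> pd.DataFrame:
    """Sleep records straight from an hourly count grid (one row per person)."""
    rows = []
    for i, pid in enumerate(ids):
        grid = (np.asarray(counts[i]) > 0).astype(int).reshape(-1, 24)
        for rec in records_from_grid(grid, pid, anchor_hour):
            rows.append((pid, rec.day_index, rec.sleep_hour, rec.wake_hour,
                         rec.mid_sleep_hour, rec.duration_hours))
    return pd.DataFrame(
        rows,
        columns=["user", "day", "sleep_hour", "wake_hour", "mid_sleep_hour", "duration"],
    )


def _noon_key(hour) -> float:
    return (np.asarray(hour, dtype=float) - ANCHOR_HOUR) % 24


def circular_mean_hour(hours) -> float:
    """Mean of clock hours on the 24-hour circle, in [0, 24)."""
    ang = np.asarray(hours, dtype=float) * (2 * np.pi / 24)
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    hour = float((mean * 24 / (2 * np.pi)) % 24)
    return 0.0 if hour >= 24.0 else hour  # (-eps) % 24 rounds to 24.0


def mode_hour(hours) -> int:
    """Most frequent hour; ties resolved toward the circular mean, then by
    earliest hour in noon-anchored order."""
    hours = np.asarray(hours, dtype=int)
    values, counts = np.unique(hours, return_counts=True)
    candidates = values[counts == counts.max()]
    if len(candidates) == 1:
        return int(candidates[0])
    mean = circular_mean_hour(hours)
    diff = np.abs(candidates - mean)
    circ_dist = np.minimum(diff % 24, (-diff) % 24)
    order = np.lexsort((_noon_key(candidates), circ_dist))
    return int(candidates[order[0]])


def summarize_sleep(records) -> SleepSummary:
    """Per-person typical (modal) sleep, wake, mid-sleep hours and mean duration."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        frame = pd.DataFrame(
            {
                "user": [r.participant_id for r in records],
                "sleep_hour": [r.sleep_hour for r in records],
                "wake_hour": [r.wake_hour for r in records],
                "mid_sleep_hour": [r.mid_sleep_hour for r in records],
                "duration": [r.duration_hours for r in records],
            }
        )
    if len(frame) == 0:
        raise ValueError("no sleep records to summarize")
    users = frame["user"].unique()
    if len(users) != 1:
        raise ValueError("summarize_sleep expects records of a single participant")
    return SleepSummary(
        str(users[0]),
        mode_hour(frame["sleep_hour"]),
        mode_hour(frame["wake_hour"]),
        mode_hour(np.floor(frame["mid_sleep_hour"]).astype(int)),
        float(frame["duration"].mean()),
    )


def sleep_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """One summary row per participant.

    Columns: ``user, typical_sleep, typical_wake, typical_mid_sleep,
    mean_duration``.
    """
    rows = []
    for user, group in records.groupby("user", sort=False):
        s = summarize_sleep(group)
        rows.append((s.participant_id, s.typical_sleep, s.typical_wake,
                     s.typical_mid_sleep, s.mean_duration))
    return pd.DataFrame(
        rows,
        columns=["user", "typical_sleep", "typical_wake", "typical_mid_sleep", "mean_duration"],
    )
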