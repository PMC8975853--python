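"""Participant-inclusion filters and normalized 168-bin weekly activity rhythms.

Each retained participant's screen-on events are aggregated over the whole
observation window into hour-of-week bins (Monday 00h = bin 0 ... Sunday
23h = bin 167) and normalized to fractions, giving a weekly *activity
rhythm*.  The population of rhythms is stacked into the N x 168 matrix X
that the NMF decomposition factorizes.

Inclusion criteria (defaults follow the standard protocol for this kind of
screen-event cohort): a participant is kept if (1) they have at least one
screen-on event on >= 80% of the window's days, and (2) they average at
least 280 combined screen-on + screen-off events per week over the window.
Only screen-on events enter the rhythms themselves; screen-off events count
solely toward criterion (2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import HOURS_PER_WEEK, EventLog

logger = logging.getLogger(__name__)


@dataclass
class WeeklyProfile:
    """One participant's normalized hour-of-week activity fractions."""

    participant_id: str
    fractions: np.ndarray
    total_events: int

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (HOURS_PER_WEEK,):
            raise ValueError(
                f"profile must have {HOURS_PER_WEEK} bins, got {self.fractions.shape}"
            )
        if (self.fractions < 0).any():
            raise ValueError("profile fractions must be non-negative")
        if self.total_events > 0 and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("profile fractions must sum to 1")


@dataclass
class ProfileMatrix:
    """The N x 168 population matrix of weekly activity rhythms."""

    X: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != HOURS_PER_WEEK:
            raise ValueError(f"X must be N x {HOURS_PER_WEEK}, got {self.X.shape}")
        if self.X.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length must match number of rows")
        if (self.X < 0).any():
            raise ValueError("X must be non-negative")

    @property
    def n_participants(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"h{j:03d}" for j in range(HOURS_PER_WEEK)]
        frame = pd.DataFrame(self.X, columns=cols)
        frame.insert(0, "user", self.row_ids)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProfileMatrix":
        frame = pd.read_csv(path, dtype={"user": str})
        cols = [f"h{j:03d}" for j in range(HOURS_PER_WEEK)]
        return cls(frame[cols].to_numpy(float), list(frame["user"]))


def filter_participants(
    log: EventLog,
    min_day_fraction: float = 0.80,
    min_weekly_events: float = 280.0,
) -> EventLog:
    """Apply the two inclusion criteria and return the restricted log.

    Criterion 1: >= 1 screen-on event on at least ``min_day_fraction`` of
    the window's days.  Criterion 2: mean combined on+off events per week
    >= ``min_weekly_events``, averaged over the whole window.
    """
    if len(log) == 0:
        raise ValueError("cannot filter an empty event log")
    n_days = log.n_days
    n_weeks = n_days / 7.0

    on = log.screen_on()
    active_days = on.groupby("user")["timestamp"].apply(lambda s: s.dt.date.nunique())
    total_events = log.data.groupby("user").size()

    keep = []
    for user in log.participants:
        days = int(active_days.get(user, 0))
        weekly = float(total_events.get(user, 0)) / n_weeks
        if days >= min_day_fraction * n_days and weekly >= min_weekly_events:
            keep.append(user)
    logger.info("retained %d / %d participants", len(keep), len(log.participants))
    if not keep:
        logger.warning("inclusion filters removed every participant")
    return log.restrict(keep)


def build_weekly_profile(timestamps, participant_id: str = "") -> WeeklyProfile:
    """Bin one participant's screen-on timestamps into a normalized rhythm.

    Counts events per hour-of-week over the whole window and divides by the
    total count, so the 168 fractions sum to one.
    """
    ts = pd.Series(pd.to_datetime(pd.Series(list(timestamps))))
    if len(ts) == 0:
        raise ValueError(f"participant {participant_id!r} has no screen-on events")
    bins = 24 * ts.dt.weekday.to_numpy() + ts.dt.hour.to_numpy()
    counts = np.bincount(bins, minlength=HOURS_PER_WEEK).astype(float)
    return WeeklyProfile(participant_id, counts / counts.sum(), int(len(ts)))


def profiles_from_log(log: EventLog) -> ProfileMatrix:
    """Build one weekly profile per participant and assemble the matrix X."""
    on = log.screen_on()
    profs = [
        build_weekly_profile(group["timestamp"], user)
        for user, group in on.groupby("user", sort=False)
    ]
    return assemble_matrix(profs)


def assemble_matrix(profiles) -> ProfileMatrix:
    """Stack weekly profiles into the N x 168 matrix, preserving input order."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to assemble")
    ids = [p.participant_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate participant ids: {dupes}")
    return ProfileMatrix(np.vstack([p.fractions for p in profiles]), ids)


def population_average(matrix: ProfileMatrix) -> np.ndarray:
    """Column-wise mean rhythm of the population; sums to one."""
    if matrix.n_participants < 1:
        raise ValueError("empty profile matrix")
    return matrix.X.mean(axis=0)
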