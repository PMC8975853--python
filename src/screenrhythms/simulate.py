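"""Synthetic screen-event populations with planted ground truth.

Real screen-event cohorts are rarely shareable, so every pipeline stage is
exercised on simulated logs whose generating truth is known.  Each
simulated person mixes four diurnal archetype rhythms — morning (~08h),
noon (~13h), evening (~19h) and night (~23-01h) peaks — modulated across
the week (morning/noon damped on weekends, evening damped Friday/Saturday,
night flat).  Mixing weights live on the simplex: each person is assigned a
dominant chronotype (noon and evening types most prevalent) and draws
admixed weights concentrated on it, so the population forms a continuous
spectrum with latent chronotype groups.  A nightly sleep
window zeroes the person's intensity; its onset is coupled positively to
the night weight and its end negatively to the morning weight, so that
night owls go to bed later and morning types wake earlier.  Hourly event
counts are Poisson draws from the resulting inhomogeneous intensity, and
every screen-on event is paired with one screen-off event.

The defaults describe the reference population used throughout the test
suite: 200 participants, 50 weeks, 300 screen-on events per week.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import HOURS_PER_WEEK, EventLog
from .profiles import ProfileMatrix

ARCHETYPE_NAMES = ("morning", "noon", "evening", "night")
ARCHETYPE_PEAKS = {"morning": 8.0, "noon": 13.0, "evening": 19.0, "night": 23.5}

#: weekday multipliers per archetype (Mon..Sun); weekend damping for the
#: daytime archetypes, Friday/Saturday damping for the evening one
WEEK_MODULATION = {
    "morning": (1, 1, 1, 1, 1, 0.7, 0.7),
    "noon": (1, 1, 1, 1, 1, 0.7, 0.7),
    "evening": (1, 1, 1, 1, 0.7, 0.7, 1),
    "night": (1, 1, 1, 1, 1, 1, 1),
}


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated cohort."""

    n_participants: int = 200
    n_weeks: int = 50
    events_per_week_mean: float = 300.0
    archetype_sigma: float = 2.0  # hours; width of the circular-Gaussian bumps
    #: relative prevalence of the four dominant chronotypes (morning, noon,
    #: evening, night); the rare morning/night types give those weights the
    #: skewed low-mass histograms seen in such cohorts
    chronotype_prevalence: tuple = (2.0, 5.0, 5.0, 2.0)
    #: per-person weights ~ Dirichlet(base + boost on the dominant archetype)
    admixture_base: float = 1.5
    admixture_boost: float = 2.5
    sleep_base_hour: float = 0.5  # typical student onset ~00:30
    sleep_night_slope: float = 10.0  # hours later per unit excess night weight
    wake_base_hour: float = 8.5
    wake_morning_slope: float = 8.0  # hours earlier per unit excess morning weight
    sleep_jitter_hours: int = 1  # nightly +/- jitter on onset and wake (hours)
    min_sleep_hours: int = 4
    max_sleep_hours: int = 12
    guarantee_presence: bool = False  # force >=1 event in every non-sleep hour
    n_noncompliant: int = 0  # extra sparse/intermittent users that fail the filters
    start_date: dt.date = dt.date(2014, 1, 6)  # a Monday
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chronotype_prevalence) != 4 or any(
            a <= 0 for a in self.chronotype_prevalence
        ):
            raise ValueError("chronotype_prevalence must be 4 positive values")
        if self.admixture_base <= 0 or self.admixture_boost < 0:
            raise ValueError("invalid admixture parameters")
        if self.events_per_week_mean <= 0:
            raise ValueError("events_per_week_mean must be positive")
        if self.start_date.weekday() != 0:
            raise ValueError("start_date must be a Monday")

    @property
    def n_days(self) -> int:
        return 7 * self.n_weeks


@dataclass
class GroundTruth:
    """Planted quantities aligned one-to-one with the emitted participants."""

    participant_ids: list
    weights: np.ndarray  # (N, 4), the Dirichlet draws on the simplex, archetype order
    #: mixture shares of the *emitted* intensity: the Dirichlet draws reweighted
    #: by the archetype mass that survives each person's sleep masking.  This is
    #: the share of observed activity per archetype, i.e. the quantity the
    #: weight-normalized NMF estimates.
    effective_weights: np.ndarray  # (N, 4), rows on the simplex
    archetypes: dict  # name -> 168-vector template, each summing to 1
    sleep_hours: np.ndarray  # (N, n_nights) planted nightly onset clock hour
    wake_hours: np.ndarray  # (N, n_nights) planted wake clock hour
    durations: np.ndarray  # (N, n_nights) planted sleep length in hours
    typical_sleep: np.ndarray  # (N,) jitter-free onset clock hour
    typical_wake: np.ndarray  # (N,) jitter-free wake clock hour
    dominant: np.ndarray  # (N,) index of each person's dominant archetype
    compliant: np.ndarray  # (N,) bool: expected to survive the inclusion filters

    def to_json(self, path) -> None:
        payload = {
            "participant_ids": list(self.participant_ids),
            "weights": self.weights.tolist(),
            "effective_weights": self.effective_weights.tolist(),
            "archetype_names": list(ARCHETYPE_NAMES),
            "typical_sleep": self.typical_sleep.tolist(),
            "typical_wake": self.typical_wake.tolist(),
            "dominant": self.dominant.tolist(),
            "compliant": self.compliant.astype(bool).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def archetype_templates(sigma: float = 2.0) -> dict:
    """The four 168-bin intensity templates, each normalized to sum to one.

    Each is a circular-Gaussian bump on hour-of-day repeated over the seven
    days with the archetype's weekday modulation.
    """
    hours = np.arange(24, dtype=float)
    templates = {}
    for name in ARCHETYPE_NAMES:
        mu = ARCHETYPE_PEAKS[name]
        delta = np.minimum(np.abs(hours - mu), 24 - np.abs(hours - mu))
        daily = np.exp(-0.5 * (delta / sigma) ** 2)
        week = np.concatenate([m * daily for m in WEEK_MODULATION[name]])
        templates[name] = week / week.sum()
    return templates


def _draw_weights(config: GeneratorConfig, n: int, rng: np.random.Generator):
    """Simplex weights concentrated on a per-person dominant chronotype."""
    prev = np.asarray(config.chronotype_prevalence, dtype=float)
    dominant = rng.choice(4, size=n, p=prev / prev.sum())
    alpha = np.full((n, 4), config.admixture_base)
    alpha[np.arange(n), dominant] += config.admixture_boost
    gamma = rng.gamma(alpha)
    return gamma / gamma.sum(axis=1, keepdims=True), dominant


def _mean_weights(config: GeneratorConfig) -> np.ndarray:
    """Population mean of the planted weights, in closed form."""
    prev = np.asarray(config.chronotype_prevalence, dtype=float)
    prev = prev / prev.sum()
    total = 4 * config.admixture_base + config.admixture_boost
    dom_mean = (config.admixture_base + config.admixture_boost) / total
    other_mean = config.admixture_base / total
    return prev * dom_mean + (1 - prev) * other_mean


def _plant_population(config: GeneratorConfig, rng: np.random.Generator):
    """Draw weights, sleep schedules and hourly Poisson counts."""
    n, n_days = config.n_participants, config.n_days
    total_hours = n_days * 24
    templates = archetype_templates(config.archetype_sigma)
    A = np.vstack([templates[name] for name in ARCHETYPE_NAMES])  # (4, 168)

    weights, dominant = _draw_weights(config, n, rng)
    w_mean = _mean_weights(config)

    typ_sleep = config.sleep_base_hour + config.sleep_night_slope * (
        weights[:, 3] - w_mean[3]
    )
    typ_wake = config.wake_base_hour - config.wake_morning_slope * (
        weights[:, 0] - w_mean[0]
    )

    n_nights = n_days
    j = config.sleep_jitter_hours
    sleep_jit = rng.integers(-j, j + 1, size=(n, n_nights)) if j else np.zeros((n, n_nights), int)
    wake_jit = rng.integers(-j, j + 1, size=(n, n_nights)) if j else np.zeros((n, n_nights), int)
    sleep_hours = (np.rint(typ_sleep)[:, None].astype(int) + sleep_jit) % 24
    wake_hours = (np.rint(typ_wake)[:, None].astype(int) + wake_jit) % 24
    durations = (wake_hours - sleep_hours) % 24
    durations = np.clip(durations, config.min_sleep_hours, config.max_sleep_hours)
    wake_hours = (sleep_hours + durations) % 24

    lam_week = config.events_per_week_mean * (weights @ A)  # (N, 168)
    reps = int(np.ceil(total_hours / HOURS_PER_WEEK))
    lam = np.tile(lam_week, (1, reps))[:, :total_hours]

    # zero the intensity inside every planted sleep window
    awake = np.ones((n, total_hours), dtype=bool)
    night_day = np.arange(n_nights)
    start_abs = np.where(
        sleep_hours >= 12,
        night_day[None, :] * 24 + sleep_hours,
        (night_day[None, :] + 1) * 24 + sleep_hours,
    )
    offs = np.arange(int(durations.max()) if durations.size else 0)
    idx = start_abs[:, :, None] + offs[None, None, :]
    covered = (offs[None, None, :] < durations[:, :, None]) & (idx < total_hours)
    for i in range(n):
        awake[i, idx[i][covered[i]]] = False
    lam = np.where(awake, lam, 0.0)
    # renormalize so masking does not change the expected weekly event count
    target = config.events_per_week_mean * config.n_weeks
    lam *= target / lam.sum(axis=1, keepdims=True)

    counts = rng.poisson(lam)
    if config.guarantee_presence:
        counts = np.where(awake, np.maximum(counts, 1), counts)

    # share of each person's emitted intensity contributed by each archetype
    B = np.tile(A, (1, reps))[:, :total_hours]  # (4, T)
    surviving_mass = awake @ B.T  # (N, 4)
    eff = weights * surviving_mass
    eff /= eff.sum(axis=1, keepdims=True)

    ids = [f"p{i:03d}" for i in range(n)]
    gt = GroundTruth(
        ids, weights, eff, templates, sleep_hours, wake_hours, durations,
        np.rint(typ_sleep).astype(int) % 24, np.rint(typ_wake).astype(int) % 24,
        dominant, np.ones(n, dtype=bool),
    )
    return counts, gt


def _noncompliant_counts(config: GeneratorConfig, rng: np.random.Generator):
    """Sparse, intermittent users violating both inclusion criteria."""
    n = config.n_noncompliant
    total_hours = config.n_days * 24
    templates = archetype_templates(config.archetype_sigma)
    A = np.vstack([templates[name] for name in ARCHETYPE_NAMES])
    weights, _ = _draw_weights(config, n, rng)
    lam_week = 60.0 * (weights @ A)  # ~120 on+off events/week, below 280
    reps = int(np.ceil(total_hours / HOURS_PER_WEEK))
    lam = np.tile(lam_week, (1, reps))[:, :total_hours]
    active_day = rng.random((n, config.n_days)) < 0.5  # used on ~half the days
    lam *= np.repeat(active_day, 24, axis=1)
    return rng.poisson(lam), [f"nc{i:03d}" for i in range(n)]


def _append_noncompliant(gt: GroundTruth, nc_ids: list) -> GroundTruth:
    pad = np.full((len(nc_ids), 4), np.nan)
    return GroundTruth(
        list(gt.participant_ids) + nc_ids,
        np.vstack([gt.weights, pad]),
        np.vstack([gt.effective_weights, pad]),
        gt.archetypes, gt.sleep_hours, gt.wake_hours, gt.durations,
        gt.typical_sleep, gt.typical_wake,
        np.concatenate([gt.dominant, np.full(len(nc_ids), -1, dtype=int)]),
        np.concatenate([gt.compliant, np.zeros(len(nc_ids), dtype=bool)]),
    )


def generate_hourly_counts(config: GeneratorConfig):
    """Fast path: hourly screen-on count grid (N, n_days*24) plus ground truth.

    Equivalent to binning the events of :func:`generate_population` by hour;
    used where event-level timestamps are not needed.
    """
    rng = np.random.default_rng(config.seed)
    counts, gt = _plant_population(config, rng)
    if config.n_noncompliant:
        nc_counts, nc_ids = _noncompliant_counts(config, rng)
        counts = np.vstack([counts, nc_counts])
        gt = _append_noncompliant(gt, nc_ids)
    return counts, gt


def counts_to_profiles(counts: np.ndarray, ids) -> ProfileMatrix:
    """Fold an hourly count grid to normalized 168-bin weekly profiles.

    Identical to building profiles from the materialized event log, since
    profile binning only uses each event's hour of week.
    """
    counts = np.asarray(counts)
    n, total_hours = counts.shape
    how = np.arange(total_hours) % HOURS_PER_WEEK
    X = np.zeros((n, HOURS_PER_WEEK))
    np.add.at(X.T, how, counts.T)
    totals = X.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("participant with zero events")
    return ProfileMatrix(X / totals, list(ids))


def counts_to_log(counts: np.ndarray, ids, config: GeneratorConfig,
                  rng: np.random.Generator) -> EventLog:
    """Materialize an hourly count grid into a timestamped on/off event log."""
    start = pd.Timestamp(config.start_date)
    frames = []
    for i, pid in enumerate(ids):
        hours = np.repeat(np.arange(counts.shape[1]), counts[i])
        u = np.sort(rng.integers(0, 3600, size=(len(hours), 2)), axis=1)
        on = start + pd.to_timedelta(hours * 3600 + u[:, 0], unit="s")
        off = start + pd.to_timedelta(hours * 3600 + np.minimum(u[:, 1] + 1, 3599), unit="s")
        frames.append(pd.DataFrame({
            "user": pid,
            "event": np.repeat(["screen_on", "screen_off"], len(hours)),
            "timestamp": np.concatenate([on.to_numpy(), off.to_numpy()]),
        }))
    data = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        {"user": pd.Series(dtype=str), "event": pd.Series(dtype=str),
         "timestamp": pd.Series(dtype="datetime64[ns]")}
    )
    data = data.sort_values(["user", "timestamp"], kind="mergesort")
    window = (config.start_date, config.start_date + dt.timedelta(days=config.n_days - 1))
    return EventLog(data.reset_index(drop=True), window)


def generate_population(config: GeneratorConfig) -> tuple[EventLog, GroundTruth]:
    """Generate a full timestamped event log with its ground truth.

    Fully reproducible from ``config.seed``: the same config yields a
    byte-identical log.
    """
    rng = np.random.default_rng(config.seed)
    counts, gt = _plant_population(config, rng)
    ids = list(gt.participant_ids)
    if config.n_noncompliant:
        nc_counts, nc_ids = _noncompliant_counts(config, rng)
        counts = np.vstack([counts, nc_counts])
        ids = ids + nc_ids
        gt = _append_noncompliant(gt, nc_ids)
    log = counts_to_log(counts, ids, config, rng)
    return log, gt


def match_archetypes(H_unit: np.ndarray, archetypes: dict):
    """Best bipartite matching of recovered components to planted archetypes.

    Returns ``(columns, cosines)``: for each archetype in
    :data:`ARCHETYPE_NAMES` order, the index of its matched H column and the
    cosine similarity of the pair.  Matching maximizes total cosine
    similarity (Hungarian assignment).
    """
    from scipy.optimize import linear_sum_assignment

    A = np.vstack([archetypes[name] for name in ARCHETYPE_NAMES])
    H = np.asarray(H_unit, dtype=float).T  # (K, 168)
    cos = (A @ H.T) / (
        np.linalg.norm(A, axis=1)[:, None] * np.linalg.norm(H, axis=1)[None, :]
    )
    rows, cols = linear_sum_assignment(-cos)
    return cols, cos[rows, cols]


def degenerate_cases(kind: str) -> EventLog:
    """Tiny one-week fixture logs for filter and sleep-inference edge cases."""
    start = dt.date(2014, 1, 6)  # Monday
    window = (start, start + dt.timedelta(days=6))

    def log_from(times):
        data = pd.DataFrame({
            "user": "u0",
            "event": "screen_on",
            "timestamp": pd.to_datetime(times),
        })
        return EventLog(data.sort_values("timestamp").reset_index(drop=True), window)

    base = dt.datetime(2014, 1, 6)
    if kind == "empty":
        data = pd.DataFrame({"user": pd.Series(dtype=str),
                             "event": pd.Series(dtype=str),
                             "timestamp": pd.Series(dtype="datetime64[ns]")})
        return EventLog(data, window)
    if kind == "single_event":
        return log_from([base + dt.timedelta(hours=10, minutes=15)])
    if kind == "always_on":
        return log_from([base + dt.timedelta(hours=h) for h in range(7 * 24)])
    if kind == "never_on_weekends":
        times = [
            base + dt.timedelta(days=d, hours=h)
            for d in range(5)  # Monday..Friday only
            for h in range(8, 21)
        ]
        return log_from(times)
    raise ValueError(f"unknown degenerate case {kind!r}")
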