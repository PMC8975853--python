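"""End-to-end run orchestration: filter -> profiles -> rank selection ->
NMF -> weights -> sleep inference -> associations, with a run manifest.

Every numeric output of a run is reproducible from (config, master seed,
input file): each randomized stage receives its own seed derived
deterministically from the master seed via a fixed counter scheme
(``stage_seed(master, i)`` for stage index i).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import yaml

from . import __version__
from .associations import sleep_weight_associations, weight_correlation_matrix
from .events import read_event_log, week_window
from .nmf import RhythmNMF
from .profiles import filter_participants, profiles_from_log
from .rank import select_k
from .sleep import sleep_records, sleep_summaries

logger = logging.getLogger(__name__)

# stage indices of the seed-derivation counter scheme
STAGE_SIMULATE, STAGE_SELECT_K, STAGE_NMF = 0, 1, 2


def stage_seed(master_seed: int, stage: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, stage]).generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class RunConfig:
    """Settings of a full pipeline run (defaults = the reference protocol)."""

    year: int = 2014
    first_week: int = 2
    last_week: int = 51
    min_day_fraction: float = 0.80
    min_weekly_events: float = 280.0
    k: int = 0  # 0 -> choose K by the cophenetic sweep
    k_min: int = 2
    k_max: int = 7
    n_restarts: int = 1000
    tol: float = 1e-6
    max_iter: int = 500
    n_consensus_runs: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig, events_path, out_dir) -> dict:
    """Execute the full analysis and write every artifact plus a manifest.

    Returns the manifest dict.  Artifacts: ``profiles.csv``,
    ``k_selection.csv`` (when K is swept), ``W.csv`` / ``H.csv`` /
    ``decomposition.json``, ``weights.csv`` (normalized), sleep record and
    summary CSVs, the two association CSVs, and ``manifest.json``.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = week_window(config.year, config.first_week, config.last_week)

    log = read_event_log(events_path, window)
    n_raw = len(log.participants)
    logger.info("stage filter: %d raw participants", n_raw)
    kept = filter_participants(log, config.min_day_fraction, config.min_weekly_events)

    matrix = profiles_from_log(kept)
    matrix.to_csv(out / "profiles.csv")

    if config.k:
        k_used = config.k
    else:
        sel = select_k(
            matrix, config.k_min, config.k_max, n_runs=config.n_consensus_runs,
            seed=stage_seed(config.seed, STAGE_SELECT_K),
            tol=config.tol, max_iter=config.max_iter,
        )
        sel.to_csv(out / "k_selection.csv")
        k_used = sel.best_k

    model = RhythmNMF(matrix, k_used)
    res = model.fit_multistart(
        n_restarts=config.n_restarts, seed=stage_seed(config.seed, STAGE_NMF),
        tol=config.tol, max_iter=config.max_iter,
    )
    res.save(out)
    weights = res.normalized_weights()
    weights.to_frame().to_csv(out / "weights.csv", index=False)

    records = sleep_records(kept)
    records.to_csv(out / "sleep_records.csv", index=False)
    summaries = sleep_summaries(records)
    summaries.to_csv(out / "sleep_summary.csv", index=False)

    weight_correlation_matrix(weights).to_csv(out / "weight_correlations.csv")
    assoc = sleep_weight_associations(weights, summaries)
    assoc.to_csv(out / "sleep_associations.csv")

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_raw_participants": n_raw,
        "n_retained_participants": matrix.n_participants,
        "k": k_used,
        "error": res.error,
        "n_sleep_records": int(len(records)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
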