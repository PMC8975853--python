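"""Non-negative matrix factorization of weekly activity rhythms.

The population matrix X (N participants x 168 hours of the week) is
approximated as X ~ W H^T with W (N x K) the per-person component weights
and H (168 x K) the K non-negative basis rhythms, by minimizing the squared
Frobenius objective

    E = 1/2 || X - W H^T ||_F^2.

The optimizer is hierarchical alternating least squares (HALS): each column
of W and H in turn gets its exact non-negatively-projected least-squares
update, which makes E non-increasing across full sweeps.  Initialization is
random, so the factorization is run from many random seeds and the run with
the smallest final error is kept.

Because W H^T is invariant to rescaling a component and inversely rescaling
its weights, weights are made comparable by first moving each H column's
total mass into W (so every component is a unit-mass rhythm) and then
normalizing each person's K weights to sum to one.

:class:`RhythmNMF` / :class:`RhythmNMFResults` present the same machinery
as a model object fitted to a profile matrix, in the style of statsmodels.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import HOURS_PER_WEEK
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

#: Entries below this value are treated as zero.  During HALS sweeps factor
#: entries are clipped *at* EPS rather than 0 so components cannot die
#: permanently; the final factors are hard-clipped to exact zeros below it.
EPS = 1e-12

#: Hour-of-day band edges for naming components by their mean daily peak.
LABEL_BANDS = {"morning": (5, 10), "noon": (10, 15), "evening": (15, 21)}


@dataclass
class Decomposition:
    """Factors and bookkeeping of one NMF run."""

    W: np.ndarray
    H: np.ndarray
    k: int
    error: float
    seed: int
    n_iterations: int
    objective_history: list = field(default_factory=list, repr=False)
    row_ids: list | None = None

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H.T

    def recompute_error(self, X: np.ndarray) -> float:
        return frobenius_error(X, self.W, self.H)


@dataclass
class NormalizedWeights:
    """Per-person component weights rescaled to sum to one.

    ``weights`` rows live on the K-simplex; ``component_order`` carries the
    peak-hour labels of the matching H columns; ``H_unit`` holds the
    unit-mass basis rhythms (each column sums to one).
    """

    weights: np.ndarray
    component_order: list
    row_ids: list | None = None
    H_unit: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.weights, columns=self.component_order)
        if self.row_ids is not None:
            frame.insert(0, "user", self.row_ids)
        return frame


def frobenius_error(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """The objective E = 1/2 ||X - W H^T||_F^2."""
    return 0.5 * float(np.linalg.norm(X - W @ H.T) ** 2)


def _as_matrix(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, ProfileMatrix):
        return X.X, X.row_ids
    X = np.asarray(X, dtype=float)
    return X, None


def _hals_sweep(X, W, H) -> None:
    """One full HALS sweep: exact projected updates of every W then H column."""
    HtH = H.T @ H
    XH = X @ H
    for k in range(W.shape[1]):
        d = HtH[k, k]
        if d <= EPS:
            continue
        W[:, k] = np.maximum(EPS, W[:, k] + (XH[:, k] - W @ HtH[:, k]) / d)
    WtW = W.T @ W
    XtW = X.T @ W
    for k in range(H.shape[1]):
        d = WtW[k, k]
        if d <= EPS:
            continue
        H[:, k] = np.maximum(EPS, H[:, k] + (XtW[:, k] - H @ WtW[:, k]) / d)


def nmf_hals(
    X,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> Decomposition:
    """Factorize ``X`` into K non-negative components with HALS.

    Starts from i.i.d. uniform(0, s) factors with s = sqrt(mean(X)/K) and
    sweeps until the relative decrease of the objective falls below ``tol``
    or ``max_iter`` full sweeps have run.  The objective is non-increasing
    across sweeps.
    """
    X, row_ids = _as_matrix(X)
    n, m = X.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k must be in [1, {min(n, m)}], got {k}")
    if (X < 0).any():
        raise ValueError("X must be non-negative")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), 0.0) / k)
    if scale == 0.0:  # all-zero X: the exact factorization is zero
        W = np.zeros((n, k))
        H = np.zeros((m, k))
        return Decomposition(W, H, k, 0.0, seed, 0, [0.0], row_ids)
    W = rng.uniform(0.0, scale, size=(n, k))
    H = rng.uniform(0.0, scale, size=(m, k))

    history = [frobenius_error(X, W, H)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        _hals_sweep(X, W, H)
        err = frobenius_error(X, W, H)
        history.append(err)
        prev = history[-2]
        if prev - err < tol * max(prev, EPS):
            break
    W[W <= EPS] = 0.0
    H[H <= EPS] = 0.0
    return Decomposition(W, H, k, frobenius_error(X, W, H), seed, n_iter, history, row_ids)


def restart_seeds(master_seed: int, n_seeds: int) -> np.ndarray:
    """Deterministic per-restart integer seeds derived from a master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n_seeds) % (2**31)


def nmf_multistart(
    X,
    k: int,
    n_seeds: int = 1000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> Decomposition:
    """Run HALS from ``n_seeds`` random initializations; keep the smallest error.

    Restart seeds are derived deterministically from ``seed``, so the result
    is reproducible.  Ties go to the earliest restart.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    best: Decomposition | None = None
    for s in restart_seeds(seed, n_seeds):
        dec = nmf_hals(X, k, seed=int(s), tol=tol, max_iter=max_iter)
        if best is None or dec.error < best.error:
            best = dec
    logger.info("multistart k=%d: best error %.6g over %d restarts", k, best.error, n_seeds)
    return best


def label_components(H: np.ndarray) -> list:
    """Name each component after the hour-of-day band of its mean daily peak.

    The 168-bin component is folded to a 24-hour profile (mean over the 7
    days); its argmax hour selects a band: morning 5-10, noon 10-15,
    evening 15-21, night otherwise (21-05, wrapping midnight).  When several
    components share a band they get ordinal suffixes, ordered by earlier
    peak hour.
    """
    H = np.asarray(H, dtype=float)
    peaks = [int(np.argmax(H[:, k].reshape(7, 24).mean(axis=0))) for k in range(H.shape[1])]

    def band(p: int) -> str:
        for name, (lo, hi) in LABEL_BANDS.items():
            if lo <= p < hi:
                return name
        return "night"

    bands = [band(p) for p in peaks]
    labels = list(bands)
    for name in set(bands):
        members = [k for k, b in enumerate(bands) if b == name]
        if len(members) > 1:
            # night band wraps midnight: order its peaks from evening side
            key = (lambda k: ((peaks[k] - 12) % 24, k)) if name == "night" else (
                lambda k: (peaks[k], k)
            )
            for rank, k in enumerate(sorted(members, key=key), start=1):
                labels[k] = f"{name}_{rank}"
    return labels


def normalize_weights(dec: Decomposition) -> NormalizedWeights:
    """Move each component's mass into W, then normalize each row to unity.

    Column k of W is multiplied by the sum of column k of H while that H
    column is divided by its sum; the product W H^T is unchanged.  Each
    person's rescaled weights are then divided by their sum so the K
    weights sum to one.
    """
    mass = dec.H.sum(axis=0)
    H_unit = np.where(mass > 0, dec.H / np.where(mass > 0, mass, 1.0), dec.H)
    W_scaled = dec.W * mass
    row_sums = W_scaled.sum(axis=1)
    if (row_sums <= 0).any():
        bad = np.flatnonzero(row_sums <= 0)
        names = [dec.row_ids[i] for i in bad] if dec.row_ids else list(map(int, bad))
        raise ValueError(f"all-zero weight rows for participants: {names}")
    weights = W_scaled / row_sums[:, None]
    return NormalizedWeights(weights, label_components(dec.H), dec.row_ids, H_unit)


class RhythmNMF:
    """NMF model of a population's weekly activity rhythms.

    Parameters
    ----------
    profiles
        A :class:`~screenrhythms.profiles.ProfileMatrix` or a non-negative
        ``(N, 168)`` array of row-normalized rhythms.
    k
        Number of components to extract.
    """

    def __init__(self, profiles, k: int):
        self.X, self.row_ids = _as_matrix(profiles)
        if not 1 <= k <= min(self.X.shape):
            raise ValueError(f"k must be in [1, {min(self.X.shape)}]")
        self.k = k

    @classmethod
    def from_profiles(cls, profiles: ProfileMatrix, k: int) -> "RhythmNMF":
        return cls(profiles, k)

    def fit(self, seed: int = 0, tol: float = 1e-6, max_iter: int = 500) -> "RhythmNMFResults":
        dec = nmf_hals(self.X, self.k, seed=seed, tol=tol, max_iter=max_iter)
        dec.row_ids = self.row_ids
        return RhythmNMFResults(self, dec)

    def fit_multistart(
        self, n_restarts: int = 1000, seed: int = 0, tol: float = 1e-6, max_iter: int = 500
    ) -> "RhythmNMFResults":
        dec = nmf_multistart(self.X, self.k, n_seeds=n_restarts, seed=seed, tol=tol, max_iter=max_iter)
        dec.row_ids = self.row_ids
        return RhythmNMFResults(self, dec)


class RhythmNMFResults:
    """Fitted factors, weight normalization, labels, summary and plotting."""

    def __init__(self, model: RhythmNMF, decomposition: Decomposition):
        self.model = model
        self.decomposition = decomposition

    W = property(lambda self: self.decomposition.W)
    H = property(lambda self: self.decomposition.H)
    k = property(lambda self: self.decomposition.k)
    error = property(lambda self: self.decomposition.error)

    def normalized_weights(self) -> NormalizedWeights:
        return normalize_weights(self.decomposition)

    def component_labels(self) -> list:
        return label_components(self.H)

    def reconstruction(self) -> np.ndarray:
        return self.decomposition.reconstruction()

    def summary(self) -> str:
        labels = self.component_labels()
        nw = self.normalized_weights()
        lines = [
            "Weekly activity rhythm NMF",
            "=" * 42,
            f"participants (N): {self.model.X.shape[0]:>6d}",
            f"hour bins (M):    {self.model.X.shape[1]:>6d}",
            f"components (K):   {self.k:>6d}",
            f"objective E:      {self.error:>12.6g}",
            f"sweeps:           {self.decomposition.n_iterations:>6d}",
            "-" * 42,
            f"{'component':<12}{'peak hour':>10}{'mean weight':>14}",
        ]
        for j, lab in enumerate(labels):
            peak = int(np.argmax(self.H[:, j].reshape(7, 24).mean(axis=0)))
            lines.append(f"{lab:<12}{peak:>10d}{nw.weights[:, j].mean():>14.3f}")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write W.csv, H.csv and a JSON sidecar with run metadata."""
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        labels = self.component_labels()
        w_frame = pd.DataFrame(self.W, columns=labels)
        ids = self.decomposition.row_ids
        w_frame.insert(0, "user", ids if ids is not None else range(len(w_frame)))
        w_frame.to_csv(out / "W.csv", index=False)
        pd.DataFrame(self.H, columns=labels).to_csv(out / "H.csv", index=False)
        meta = {
            "k": self.k,
            "seed": int(self.decomposition.seed),
            "error": self.error,
            "n_iterations": self.decomposition.n_iterations,
        }
        (out / "decomposition.json").write_text(json.dumps(meta, indent=2))

    def plot_components(self, ax=None):
        """Line plot of the unit-mass components over the 168 hours."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        nw = self.normalized_weights()
        for j, lab in enumerate(nw.component_order):
            ax.plot(np.arange(HOURS_PER_WEEK), nw.H_unit[:, j], label=lab)
        ax.set_xlabel("hour of week (0 = Monday 00h)")
        ax.set_ylabel("fraction of events")
        ax.legend(fontsize=8)
        return ax
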